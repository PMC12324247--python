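"""Per-stimulus memorability scoring from trial-level recognition data.

Raw 6-point responses (1 = "definitely yes" ... 6 = "definitely no") are
reverse-coded once at scoring time (r -> 7 - r) so that higher values mean
greater confidence the item was seen.  A stimulus's memorability within a
group is the mean reverse-coded response when tested as an old item minus
the mean when tested as a new item (range -5 to 5); its prediction score is
the mean reverse-coded encoding-phase response (range 1 to 6).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

TRIAL_COLUMNS = ("participant", "group", "phase", "stimulus", "status", "response")
N_LEVELS = 6


def reverse_code(response):
    """Reverse-code a 1-6 response (or array of them): r -> 7 - r.

    An involution: applying it twice returns the input.
    """
    arr = np.asarray(response)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"response must be an integer in 1..6, got {response!r}")
        arr = arr.astype(int)
    bad = (arr < 1) | (arr > N_LEVELS)
    if np.any(bad):
        where = np.argwhere(bad).ravel()[:5].tolist()
        raise ValidationError(
            f"responses outside 1..{N_LEVELS} at positions {where}: "
            f"{np.asarray(arr)[bad].ravel()[:5].tolist()}"
        )
    out = 7 - arr
    return out if out.ndim else int(out)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the validated frame.

    Contract: required columns present; responses in 1..6; status is "na"
    exactly for encoding-phase rows and "old"/"new" for recognition rows.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    resp = trials["response"]
    bad = ~resp.isin(range(1, N_LEVELS + 1))
    if bad.any():
        rows = trials.index[bad][:5].tolist()
        raise ValidationError(f"responses outside 1..{N_LEVELS} at rows {rows}")
    enc = trials["phase"] == "encoding"
    if (enc & (trials["status"] != "na")).any():
        rows = trials.index[enc & (trials["status"] != "na")][:5].tolist()
        raise ValidationError(f"encoding rows must have status 'na'; offending rows {rows}")
    rec = trials["phase"] == "recognition"
    bad_status = rec & ~trials["status"].isin(["old", "new"])
    if bad_status.any():
        rows = trials.index[bad_status][:5].tolist()
        raise ValidationError(f"recognition rows must have status old/new; offending rows {rows}")
    return trials


def compute_memorability(
    trials: pd.DataFrame,
    group: str,
    min_old: int = 1,
    min_new: int = 1,
) -> pd.DataFrame:
    """Per-stimulus memorability for one group: mean old - mean new (reverse-coded).

    Returns a frame indexed by stimulus with columns
    ``group, memorability, n_old, n_new, mean_old, mean_new``.
    Raises if any stimulus tested at recognition lacks the minimum number of
    old or new observations.
    """
    validate_trials(trials)
    rec = trials[(trials["group"] == group) & (trials["phase"] == "recognition")]
    if rec.empty:
        raise ValidationError(f"no recognition trials for group {group!r}")
    coded = rec.assign(coded=7 - rec["response"].to_numpy())
    agg = (
        coded.groupby(["stimulus", "status"], observed=True)["coded"]
        .agg(["mean", "size"])
        .unstack("status")
    )
    mean_old = agg.get(("mean", "old"))
    mean_new = agg.get(("mean", "new"))
    n_old = agg.get(("size", "old"))
    n_new = agg.get(("size", "new"))
    if mean_old is None or mean_new is None:
        raise ValidationError(f"group {group!r} has no {'old' if mean_old is None else 'new'} recognition trials")
    n_old = n_old.fillna(0).astype(int)
    n_new = n_new.fillna(0).astype(int)
    deficient = sorted(agg.index[(n_old < min_old) | (n_new < min_new)])
    if deficient:
        raise ValidationError(
            f"stimuli with fewer than {min_old} old or {min_new} new observations "
            f"in group {group!r}: {deficient[:10]}"
            + ("..." if len(deficient) > 10 else "")
        )
    out = pd.DataFrame(
        {
            "group": group,
            "memorability": mean_old - mean_new,
            "n_old": n_old,
            "n_new": n_new,
            "mean_old": mean_old,
            "mean_new": mean_new,
        }
    )
    out.index.name = "stimulus"
    return out.sort_index()


def compute_predictions(trials: pd.DataFrame, group: str) -> pd.Series:
    """Per-stimulus mean reverse-coded encoding ("will I remember?") response.

    Stimuli never shown at encoding for this group are omitted (with a
    warning when they were tested at recognition).
    """
    validate_trials(trials)
    g = trials[trials["group"] == group]
    enc = g[g["phase"] == "encoding"]
    if enc.empty:
        raise ValidationError(f"no encoding trials for group {group!r}")
    pred = (7 - enc["response"]).groupby(enc["stimulus"], observed=True).mean().sort_index()
    pred.name = "prediction"
    tested = set(g.loc[g["phase"] == "recognition", "stimulus"])
    uncovered = sorted(tested - set(pred.index))
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} stimuli tested at recognition were never shown at "
            f"encoding for group {group!r}; omitted from predictions",
            stacklevel=2,
        )
    return pred


def memorability_table(trials: pd.DataFrame, groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Combined memorability + prediction table for the given (or all) groups.

    Long format: one row per (stimulus, group), columns
    ``stimulus, group, memorability, prediction, n_old, n_new, mean_old, mean_new``.
    Reverse-coding is applied here exactly once; the returned frame's
    ``attrs["reverse_coded"]`` records that.
    """
    validate_trials(trials)
    if groups is None:
        groups = sorted(trials["group"].unique())
    parts = []
    for g in groups:
        mem = compute_memorability(trials, g)
        pred = compute_predictions(trials, g)
        mem = mem.join(pred, how="left")
        parts.append(mem.reset_index())
    out = pd.concat(parts, ignore_index=True)
    out = out[["stimulus", "group", "memorability", "prediction", "n_old", "n_new", "mean_old", "mean_new"]]
    out.attrs["reverse_coded"] = True
    return out


def confidence_distribution(
    trials: pd.DataFrame,
    group: str,
    phase: str,
    status: str | None = None,
) -> np.ndarray:
    """Proportion of responses at each reverse-coded confidence level 1..6.

    ``status`` filters recognition trials to old or new items; it is ignored
    (must be None or "na") for the encoding phase.  Proportions sum to 1.
    """
    validate_trials(trials)
    sel = (trials["group"] == group) & (trials["phase"] == phase)
    if status is not None and status != "na":
        sel &= trials["status"] == status
    sub = trials[sel]
    if sub.empty:
        raise ValidationError(
            f"no trials match group={group!r}, phase={phase!r}, status={status!r}"
        )
    coded = 7 - sub["response"].to_numpy()
    counts = np.bincount(coded, minlength=N_LEVELS + 1)[1:]
    return counts / counts.sum()
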