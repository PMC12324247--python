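"""SVM recursive feature elimination with smoothed-accuracy peak selection.

At each step a linear maximum-margin classifier (hinge-loss SVM) is trained
on every split of a repeated stratified k-fold scheme (default 6 repeats x
10 folds); validation accuracies are averaged into one trace entry and the
per-dimension weight magnitudes |w_j| are averaged across all fold models.
The dimension with the smallest average |w_j| is eliminated and the loop
repeats until no dimensions remain, giving one accuracy per step.  The
trace is smoothed with a centered 7-point moving average (truncated at the
edges) and the dimensions surviving at the smoothed maximum are selected.

Features are z-scored per dimension from training-fold statistics before
each fit so weight magnitudes are comparable across dimensions; a constant
feature scales to zero and is eliminated immediately.  Fold assignment is
computed once per repeat from the run seed and reused at every step, so the
procedure is deterministic and equivariant under feature permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import _rng
from .errors import ConfigurationError, ValidationError


@dataclass
class LabeledFeatureSet:
    """Feature matrix with -1/+1 labels and dimension names."""

    features: pd.DataFrame  # index: stimulus, columns: dimension names
    labels: np.ndarray  # in {-1, +1}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {-1, 1} or len(uniq) != 2:
            raise ValidationError(f"labels must contain both -1 and +1, got {sorted(uniq)}")
        if len(self.labels) != len(self.features):
            raise ValidationError(
                f"{len(self.features)} feature rows but {len(self.labels)} labels"
            )
        if all(self.features[c].nunique() <= 1 for c in self.features.columns):
            raise ValidationError("all features are constant")

    @property
    def dimension_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass
class RFEResult:
    """Full elimination history of one recursive-elimination run."""

    elimination_order: list[str]  # first eliminated -> last
    accuracy_trace: np.ndarray  # raw mean CV accuracy per step (fractions)
    smoothed_trace: np.ndarray
    selected_subset: list[str]  # dimensions surviving at the smoothed peak
    step_weights: list[dict[str, float]]  # per step: dimension -> mean |w|

    def trace_frame(self) -> pd.DataFrame:
        d = len(self.elimination_order)
        return pd.DataFrame(
            {
                "step": np.arange(1, d + 1),
                "n_dims": np.arange(d, 0, -1),
                "acc": self.accuracy_trace,
                "smoothed_acc": self.smoothed_trace,
                "eliminated_dimension": self.elimination_order,
            }
        )

    def to_dict(self) -> dict:
        return {
            "elimination_order": self.elimination_order,
            "accuracy_trace": self.accuracy_trace.tolist(),
            "smoothed_trace": self.smoothed_trace.tolist(),
            "selected_subset": self.selected_subset,
            "step_weights": self.step_weights,
        }


def smooth_trace(trace: Sequence[float], window: int = 7) -> np.ndarray:
    """Centered moving average; the window truncates at the edges.

    Entry i is the mean of trace[max(0, i-h) : i+h+1] with h = window // 2,
    so output length equals input length.
    """
    if window % 2 == 0:
        raise ConfigurationError(f"smoothing window must be odd, got {window}")
    if window < 1:
        raise ConfigurationError(f"smoothing window must be >= 1, got {window}")
    t = np.asarray(trace, dtype=float)
    if window > len(t):
        raise ConfigurationError(f"window {window} exceeds trace length {len(t)}")
    h = window // 2
    return np.array([t[max(0, i - h): i + h + 1].mean() for i in range(len(t))])


def select_peak(result: RFEResult) -> list[str]:
    """Dimensions surviving at the smoothed-accuracy maximum.

    Trace entry k (0-based) is measured with d - k dimensions still in play;
    ties go to the earliest step, i.e. the larger subset.
    """
    step = int(np.argmax(result.smoothed_trace))  # argmax returns first max
    return list(result.elimination_order[step:])


class SVMRFE(BaseEstimator):
    """Recursive feature elimination around a linear hinge-loss SVM.

    Parameters
    ----------
    n_repeats, n_folds : the repeated stratified CV scheme (default 6 x 10).
    C : SVM regularization (margin width vs slack trade-off).
    window : odd moving-average window for the accuracy trace.
    random_state : seed for the fold shuffles.

    Attributes (after fit)
    ----------------------
    elimination_order_, accuracy_trace_, smoothed_trace_, selected_subset_,
    step_weights_, support_ (boolean mask over input feature order),
    result_ (RFEResult bundle).
    """

    def __init__(
        self,
        n_repeats: int = 6,
        n_folds: int = 10,
        C: float = 1.0,
        window: int = 7,
        random_state: int | None = None,
    ):
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.C = C
        self.window = window
        self.random_state = random_state

    def _draw_folds(self, y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """One set of stratified splits per repeat, fixed for the whole run.

        Redraws (up to 100 attempts per repeat) if any training fold lacks a
        class; with stratification this only happens in pathological cases.
        """
        splits: list[tuple[np.ndarray, np.ndarray]] = []
        idx = np.arange(len(y))
        for rep in range(self.n_repeats):
            for attempt in range(100):
                rs = _rng.derived_state(
                    self.random_state, _rng.KEY_RFE_FOLDS + rep * 101 + attempt
                )
                skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=rs)
                cand = list(skf.split(idx[:, None], y))
                if all(len(np.unique(y[tr])) == 2 for tr, _ in cand):
                    splits.extend(cand)
                    break
            else:
                raise ValidationError(
                    "could not draw stratified folds with both classes in every "
                    "training fold after 100 attempts"
                )
        return splits

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        """Run the full elimination loop; deterministic given random_state."""
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            names = (
                list(feature_names)
                if feature_names is not None
                else [f"d{j:02d}" for j in range(Xm.shape[1])]
            )
        data = LabeledFeatureSet(features=pd.DataFrame(Xm, columns=names), labels=np.asarray(y))
        yv = data.labels.astype(int)
        n, d = Xm.shape
        if n < self.n_folds:
            raise ConfigurationError(f"n={n} samples < n_folds={self.n_folds}")
        class_counts = np.unique(yv, return_counts=True)[1]
        if class_counts.min() < self.n_folds:
            raise ConfigurationError(
                f"smallest class has {class_counts.min()} samples; stratified "
                f"{self.n_folds}-fold CV needs at least {self.n_folds} per class"
            )
        splits = self._draw_folds(yv)

        remaining = list(names)
        col = {nm: j for j, nm in enumerate(names)}
        elimination_order: list[str] = []
        trace: list[float] = []
        step_weights: list[dict[str, float]] = []
        while remaining:
            sub = Xm[:, [col[nm] for nm in remaining]]
            accs = []
            absw = np.zeros(len(remaining))
            for tr, va in splits:
                mu = sub[tr].mean(axis=0)
                sd = sub[tr].std(axis=0)
                sd[sd == 0] = 1.0
                Xtr = (sub[tr] - mu) / sd
                Xva = (sub[va] - mu) / sd
                clf = SVC(kernel="linear", C=self.C)
                clf.fit(Xtr, yv[tr])
                accs.append(float(np.mean(clf.predict(Xva) == yv[va])))
                absw += np.abs(np.asarray(clf.coef_, dtype=float).ravel())
            absw /= len(splits)
            trace.append(float(np.mean(accs)))
            step_weights.append(dict(zip(remaining, absw.tolist())))
            min_w = absw.min()
            victim = min(nm for nm, w in zip(remaining, absw) if w == min_w)
            elimination_order.append(victim)
            remaining.remove(victim)

        self.elimination_order_ = elimination_order
        self.accuracy_trace_ = np.asarray(trace)
        self.smoothed_trace_ = smooth_trace(self.accuracy_trace_, self.window)
        self.step_weights_ = step_weights
        result = RFEResult(
            elimination_order=elimination_order,
            accuracy_trace=self.accuracy_trace_,
            smoothed_trace=self.smoothed_trace_,
            selected_subset=[],
            step_weights=step_weights,
        )
        result.selected_subset = select_peak(result)
        self.result_ = result
        self.selected_subset_ = result.selected_subset
        self.support_ = np.array([nm in set(result.selected_subset) for nm in names])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = d
        return self

    def get_support(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise ValidationError("estimator is not fitted")
        return self.support_


def run_rfe(
    data: LabeledFeatureSet,
    n_repeats: int = 6,
    n_folds: int = 10,
    C: float = 1.0,
    window: int = 7,
    seed: int | None = None,
) -> RFEResult:
    """Functional wrapper over SVMRFE returning the RFEResult bundle."""
    est = SVMRFE(n_repeats=n_repeats, n_folds=n_folds, C=C, window=window, random_state=seed)
    est.fit(data.features, data.labels)
    return est.result_
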