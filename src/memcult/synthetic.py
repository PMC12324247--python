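"""Synthetic two-group recognition-memory study generator.

Emulates the design of a cross-group old/new recognition experiment: two
groups of 120 participants, 600 object stimuli split into 4 subsets of 150,
each subset serving as the "old" set for 30 participants of a group and as
the "new" set for another 30.  Each participant completes 150 encoding
trials (a 6-point "will you remember this?" judgment) and 300 recognition
trials (150 old + 150 new, 6-point "did you see this?" judgment).

Responses are generated from a latent-Gaussian cumulative-link model: each
stimulus carries a latent memorability value composed of a cross-group
shared part (a linear effect of object-dimension scores plus a shared
random latent) and a group-specific part (group-specific dimension weights
plus a group random latent).  A recognition trial adds an old/new offset
and trial noise, and the resulting latent value is cut at five ordered
thresholds into a 1-6 confidence level.  Raw stored responses use the
questionnaire convention 1 = "definitely yes" ... 6 = "definitely no", so
downstream analysis reverse-codes them (7 - r).

The generator returns the true latent memorability per stimulus and group,
so every downstream stage can be checked against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _rng
from .errors import ConfigurationError, ValidationError

DEFAULT_GROUPS = ("CN", "US")


def stimulus_ids(n: int) -> list[str]:
    """Canonical stimulus identifiers s0000, s0001, ..."""
    return [f"s{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignPlan:
    """Counterbalanced stimulus-subset assignment for one group of participants.

    ``subset_assignment`` maps stimulus id -> subset index;
    ``participant_assignment`` maps participant index -> (old subset, new subset).
    The same plan is reused for every group.
    """

    n_participants_per_group: int
    n_stimuli: int
    n_subsets: int
    subset_assignment: Mapping[str, int]
    participant_assignment: Mapping[int, tuple[int, int]]
    seed: int | None

    def stimuli_in_subset(self, k: int) -> list[str]:
        return [s for s, sub in self.subset_assignment.items() if sub == k]

    @property
    def stimuli(self) -> list[str]:
        return list(self.subset_assignment)


def generate_design(
    n_participants_per_group: int,
    n_stimuli: int,
    n_subsets: int,
    seed: int | None = None,
) -> DesignPlan:
    """Randomly split stimuli into equal subsets and counterbalance old/new roles.

    Participants are distributed evenly over the ``n_subsets * (n_subsets - 1)``
    ordered (old, new) subset pairs, so each subset serves as "old" and as
    "new" for exactly ``n_participants_per_group / n_subsets`` participants.
    """
    if n_subsets < 2:
        raise ConfigurationError(f"n_subsets must be >= 2, got {n_subsets}")
    if n_stimuli % n_subsets != 0:
        raise ConfigurationError(
            f"n_stimuli={n_stimuli} is not divisible by n_subsets={n_subsets}"
        )
    n_pairs = n_subsets * (n_subsets - 1)
    if n_participants_per_group % n_pairs != 0:
        raise ConfigurationError(
            f"n_participants_per_group={n_participants_per_group} is not divisible "
            f"by the number of (old, new) subset pairs ({n_pairs})"
        )
    rng = _rng.substream(seed, _rng.KEY_DESIGN)
    ids = stimulus_ids(n_stimuli)
    perm = rng.permutation(n_stimuli)
    per_subset = n_stimuli // n_subsets
    subset_assignment = {ids[perm[i]]: i // per_subset for i in range(n_stimuli)}

    pairs = [(i, j) for i in range(n_subsets) for j in range(n_subsets) if i != j]
    reps = n_participants_per_group // n_pairs
    pair_list = pairs * reps
    order = rng.permutation(len(pair_list))
    participant_assignment = {p: pair_list[order[p]] for p in range(n_participants_per_group)}
    return DesignPlan(
        n_participants_per_group=n_participants_per_group,
        n_stimuli=n_stimuli,
        n_subsets=n_subsets,
        subset_assignment=subset_assignment,
        participant_assignment=participant_assignment,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dimension scores
# ---------------------------------------------------------------------------


@dataclass
class StimulusDimensionTable:
    """Stimulus x dimension score matrix plus a life/nonlife/mixed category map."""

    scores: pd.DataFrame  # index: stimulus id, columns: dimension names
    categories: dict[str, str]  # dimension -> {life, nonlife, mixed}

    def __post_init__(self) -> None:
        missing = [d for d in self.scores.columns if d not in self.categories]
        if missing:
            raise ValidationError(f"dimensions without a category: {missing}")

    @property
    def dimension_names(self) -> list[str]:
        return list(self.scores.columns)

    def dimensions_in_category(self, category: str) -> list[str]:
        return [d for d in self.scores.columns if self.categories[d] == category]


def load_default_dimension_metadata() -> tuple[list[str], dict[str, str]]:
    """The bundled 49 word-pair dimension labels and their category map.

    Synthetic stand-in: labels seen in published interpretable object-dimension
    sets plus same-style fillers, categorized by whether the label relates to
    living things or body parts (ambiguous labels -> mixed).
    """
    from importlib.resources import files

    path = files("memcult.fixtures").joinpath("dimension_categories_synthetic.tsv")
    with path.open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return list(df["dimension"]), dict(zip(df["dimension"], df["category"]))


def generate_dimension_space(
    n_stimuli: int,
    n_dims: int,
    dimension_names: Sequence[str],
    category_map: Mapping[str, str] | Sequence[str],
    sparsity: float = 0.7,
    seed: int | None = None,
) -> StimulusDimensionTable:
    """Nonnegative object-dimension scores: zero-truncated Gaussian with a sparsity mask.

    Each entry is |N(0,1)| with probability ``1 - sparsity`` and 0 otherwise,
    mimicking the sparse nonnegative profile of behavioral object-dimension
    embeddings.  Columns that come out constant are redrawn so every dimension
    has nonzero variance.
    """
    if len(dimension_names) != n_dims:
        raise ConfigurationError(
            f"n_dims={n_dims} but {len(dimension_names)} dimension names given"
        )
    if not isinstance(category_map, Mapping):
        if len(category_map) != n_dims:
            raise ConfigurationError(
                f"category map length {len(category_map)} != n_dims={n_dims}"
            )
        category_map = dict(zip(dimension_names, category_map))
    missing = [d for d in dimension_names if d not in category_map]
    if missing:
        raise ConfigurationError(f"category map missing dimensions: {missing}")
    if not 0.0 <= sparsity < 1.0:
        raise ConfigurationError(
            f"sparsity must be in [0, 1); got {sparsity} (1.0 would zero out "
            "whole dimensions, violating the nonzero-variance invariant)"
        )
    rng = _rng.substream(seed, _rng.KEY_DIMENSIONS)
    values = np.abs(rng.normal(size=(n_stimuli, n_dims)))
    mask = rng.random(size=(n_stimuli, n_dims)) >= sparsity
    values *= mask
    for j in range(n_dims):
        attempts = 0
        while np.var(values[:, j]) == 0.0:
            attempts += 1
            if attempts > 100:
                raise ConfigurationError(
                    f"could not draw nonconstant scores for dimension "
                    f"{dimension_names[j]!r} (n_stimuli={n_stimuli}, sparsity={sparsity})"
                )
            col = np.abs(rng.normal(size=n_stimuli))
            col *= rng.random(size=n_stimuli) >= sparsity
            values[:, j] = col
    scores = pd.DataFrame(values, index=stimulus_ids(n_stimuli), columns=list(dimension_names))
    return StimulusDimensionTable(scores=scores, categories={d: category_map[d] for d in dimension_names})


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


def generate_embeddings(
    dimensions: StimulusDimensionTable,
    embed_dim: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stimulus embeddings whose linear readout reproduces the dimension scores.

    Constructs an ``n x embed_dim`` matrix Z and a fixed map M (embed_dim x
    n_dims) such that ``scores = Z @ M + eps`` with eps ~ N(0, noise_sd^2)
    exactly.  Z mixes the minimum-norm solution with an M-null-space component
    so the embedding has full width.  Returns (embeddings, true map) so the
    map can serve as an oracle for transfer models.
    """
    X = dimensions.scores.to_numpy(dtype=float)
    n, d = X.shape
    if embed_dim < d:
        raise ConfigurationError(
            f"embed_dim={embed_dim} must be >= the number of dimensions ({d})"
        )
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = _rng.substream(seed, _rng.KEY_EMBEDDINGS)
    M = rng.normal(size=(embed_dim, d)) / np.sqrt(embed_dim)
    eps = rng.normal(scale=noise_sd, size=(n, d)) if noise_sd > 0 else np.zeros((n, d))
    target = X - eps
    Mp = np.linalg.pinv(M)  # d x embed_dim
    Z = target @ Mp
    # add a null-space component so embeddings are not confined to a d-dim subspace
    R = rng.normal(size=(n, embed_dim))
    Z += R - (R @ M) @ Mp
    emb = pd.DataFrame(Z, index=dimensions.scores.index, columns=[f"e{j:03d}" for j in range(embed_dim)])
    return emb, M


# ---------------------------------------------------------------------------
# effects and trial simulation
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """Generative parameters for latent memorability and ordinal responses.

    Latent memorability of stimulus s in group g:

        m[g, s] = x_s . shared_weights + u_s + x_s . group_weights[g] + v[g, s]

    with x_s the (column-centered) dimension scores, u ~ N(0, shared_sd^2)
    shared across groups and v ~ N(0, group_sd^2) independent per group.
    A recognition trial response is the ordinal cut (at ``thresholds``) of a
    memory-strength latent: ``m + old_offset + N(0, trial_sd^2)`` for old
    items and ``new_item_leak * m + new_offset + noise`` for new items.
    The latent drives old items fully and new items only through the
    familiarity leak (default 0) — a stimulus effect common to both
    statuses would cancel out of the old-minus-new difference score and
    leave no recoverable ground truth.  An encoding "will I remember it?"
    response is the cut of prediction_attenuation * m + noise.
    """

    shared_weights: np.ndarray | None = None
    group_specific_weights: dict[str, np.ndarray] = field(default_factory=dict)
    shared_sd: float = 0.4
    group_sd: float = 0.15
    trial_sd: float = 0.8
    old_offset: float = 1.0
    new_offset: float = -1.8
    new_item_leak: float = 0.0
    prediction_attenuation: float = 0.5
    thresholds: tuple[float, ...] = (-2.5, -1.25, 0.0, 1.25, 2.5)

    def validate(self, n_dims: int, group_ids: Sequence[str]) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if th.ndim != 1 or len(th) != 5 or not np.all(np.diff(th) > 0):
            raise ConfigurationError(
                f"thresholds must be 5 strictly increasing cut points, got {self.thresholds}"
            )
        for name, sd in (("shared_sd", self.shared_sd), ("group_sd", self.group_sd), ("trial_sd", self.trial_sd)):
            if sd < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {sd}")
        if self.shared_weights is not None and len(np.atleast_1d(self.shared_weights)) != n_dims:
            raise ConfigurationError(
                f"shared_weights length {len(np.atleast_1d(self.shared_weights))} != n_dims={n_dims}"
            )
        for g, w in self.group_specific_weights.items():
            if len(np.atleast_1d(w)) != n_dims:
                raise ConfigurationError(
                    f"group_specific_weights[{g!r}] length {len(np.atleast_1d(w))} != n_dims={n_dims}"
                )
            if g not in group_ids:
                raise ConfigurationError(f"weights given for unknown group {g!r}")


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, including its ground truth."""

    trials: pd.DataFrame  # participant, group, phase, stimulus, status, response
    dimensions: StimulusDimensionTable
    true_memorability: pd.DataFrame  # index stimulus, one column per group
    design: DesignPlan
    effect_config: EffectConfig
    group_ids: tuple[str, ...]
    seed: int | None
    embeddings: pd.DataFrame | None = None


def _ordinal_cut(latent: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Map latent values to confidence levels 1-6 (higher latent = more confident)."""
    return 1 + np.searchsorted(np.asarray(thresholds, dtype=float), latent, side="left")


def simulate_trials(
    design: DesignPlan,
    dimensions: StimulusDimensionTable,
    effect_config: EffectConfig | None = None,
    group_ids: Sequence[str] = DEFAULT_GROUPS,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate encoding + recognition trials for every participant of every group.

    Raw stored responses follow the questionnaire convention
    1 = "definitely yes" ... 6 = "definitely no" (reverse-coded downstream).
    Deterministic given the seed; trial noise draws do not depend on the
    offset values, so raising ``old_offset`` with the same seed can only
    raise responses.
    """
    cfg = effect_config if effect_config is not None else EffectConfig()
    X = dimensions.scores
    n_dims = X.shape[1]
    group_ids = tuple(group_ids)
    cfg.validate(n_dims, group_ids)
    missing = [s for s in design.stimuli if s not in X.index]
    if missing:
        raise ValidationError(f"design stimuli missing from dimension table: {missing[:5]}...")

    stim_order = design.stimuli
    Xc = X.loc[stim_order].to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    n_stim = len(stim_order)
    stim_pos = {s: i for i, s in enumerate(stim_order)}

    shared_w = (
        np.zeros(n_dims) if cfg.shared_weights is None else np.asarray(cfg.shared_weights, dtype=float)
    )
    rng_shared = _rng.substream(seed, _rng.KEY_SHARED_LATENT)
    base = Xc @ shared_w + rng_shared.normal(scale=cfg.shared_sd, size=n_stim)

    latent = {}
    for gi, g in enumerate(group_ids):
        w_g = np.asarray(
            cfg.group_specific_weights.get(g, np.zeros(n_dims)), dtype=float
        )
        rng_g = _rng.substream(seed, _rng.KEY_GROUP_LATENT + gi)
        latent[g] = base + Xc @ w_g + rng_g.normal(scale=cfg.group_sd, size=n_stim)

    subset_members = {k: design.stimuli_in_subset(k) for k in range(design.n_subsets)}

    cols: dict[str, list] = {k: [] for k in ("participant", "group", "phase", "stimulus", "status", "response")}
    th = cfg.thresholds
    for gi, g in enumerate(group_ids):
        m = latent[g]
        rng_trial = _rng.substream(seed, _rng.KEY_TRIAL_NOISE + gi)
        rng_enc = _rng.substream(seed, _rng.KEY_ENCODING_NOISE + gi)
        for p in range(design.n_participants_per_group):
            old_sub, new_sub = design.participant_assignment[p]
            pid = f"{g}_p{p:03d}"
            old_stims = subset_members[old_sub]
            new_stims = subset_members[new_sub]
            old_idx = np.fromiter((stim_pos[s] for s in old_stims), dtype=int)
            new_idx = np.fromiter((stim_pos[s] for s in new_stims), dtype=int)

            # encoding phase: participant sees their "old" subset and predicts memory
            enc_latent = (
                cfg.prediction_attenuation * m[old_idx]
                + rng_enc.normal(scale=cfg.trial_sd, size=len(old_idx))
            )
            enc_resp = 7 - _ordinal_cut(enc_latent, th)
            n_e = len(old_stims)
            cols["participant"] += [pid] * n_e
            cols["group"] += [g] * n_e
            cols["phase"] += ["encoding"] * n_e
            cols["stimulus"] += old_stims
            cols["status"] += ["na"] * n_e
            cols["response"] += enc_resp.tolist()

            # recognition phase: old then new items (order is analysis-irrelevant)
            for status, idx, stims, offset, gain in (
                ("old", old_idx, old_stims, cfg.old_offset, 1.0),
                ("new", new_idx, new_stims, cfg.new_offset, cfg.new_item_leak),
            ):
                rec_latent = gain * m[idx] + offset + rng_trial.normal(scale=cfg.trial_sd, size=len(idx))
                rec_resp = 7 - _ordinal_cut(rec_latent, th)
                n_r = len(stims)
                cols["participant"] += [pid] * n_r
                cols["group"] += [g] * n_r
                cols["phase"] += ["recognition"] * n_r
                cols["stimulus"] += stims
                cols["status"] += [status] * n_r
                cols["response"] += rec_resp.tolist()

    trials = pd.DataFrame(cols)
    trials["response"] = trials["response"].astype(int)
    true_mem = pd.DataFrame({g: latent[g] for g in group_ids}, index=stim_order)
    return SyntheticDataset(
        trials=trials,
        dimensions=dimensions,
        true_memorability=true_mem,
        design=design,
        effect_config=cfg,
        group_ids=group_ids,
        seed=seed,
    )


def plant_cultural_effects(
    dimensions: StimulusDimensionTable,
    group_ids: Sequence[str] = DEFAULT_GROUPS,
    shared_strength: float = 0.15,
    life_strength: float = 0.15,
    nonlife_strength: float = 0.12,
    n_shared: int = 12,
    n_life: int = 8,
    n_nonlife: int = 6,
    seed: int | None = None,
    **overrides,
) -> EffectConfig:
    """Build an EffectConfig with a planted group-specific effect structure.

    The first group gets positive weights on ``n_life`` life dimensions, the
    second on ``n_nonlife`` nonlife dimensions; ``n_shared`` randomly chosen
    dimensions carry weights common to both groups.  This is the default
    planted structure used by the end-to-end pipeline: a group whose
    culture-specific memorability is driven by life dimensions versus one
    driven by artifact dimensions.
    """
    rng = _rng.substream(seed, _rng.KEY_EFFECTS)
    names = dimensions.dimension_names
    n_dims = len(names)
    pos = {d: i for i, d in enumerate(names)}
    life = dimensions.dimensions_in_category("life")
    nonlife = dimensions.dimensions_in_category("nonlife")
    if n_life > len(life):
        raise ConfigurationError(f"n_life={n_life} exceeds life dimensions available ({len(life)})")
    if n_nonlife > len(nonlife):
        raise ConfigurationError(
            f"n_nonlife={n_nonlife} exceeds nonlife dimensions available ({len(nonlife)})"
        )
    shared = np.zeros(n_dims)
    chosen = rng.choice(n_dims, size=min(n_shared, n_dims), replace=False)
    shared[chosen] = shared_strength * rng.choice([-1.0, 1.0], size=len(chosen))

    g_a, g_b = group_ids[0], group_ids[1]
    w_a = np.zeros(n_dims)
    for d in rng.choice(life, size=n_life, replace=False):
        w_a[pos[d]] = life_strength
    w_b = np.zeros(n_dims)
    for d in rng.choice(nonlife, size=n_nonlife, replace=False):
        w_b[pos[d]] = nonlife_strength
    return EffectConfig(
        shared_weights=shared,
        group_specific_weights={g_a: w_a, g_b: w_b},
        **overrides,
    )


def default_dataset(seed: int | None = None, effect_config: EffectConfig | None = None,
                    with_embeddings: bool = False, embed_dim: int = 128,
                    embedding_noise_sd: float = 0.25) -> SyntheticDataset:
    """One call producing the full default-scale study (120+120 participants, 600 stimuli)."""
    names, cats = load_default_dimension_metadata()
    design = generate_design(120, 600, 4, seed=seed)
    dims = generate_dimension_space(600, 49, names, cats, sparsity=0.7, seed=seed)
    if effect_config is None:
        effect_config = plant_cultural_effects(dims, seed=seed)
    ds = simulate_trials(design, dims, effect_config, seed=seed)
    if with_embeddings:
        emb, _ = generate_embeddings(dims, embed_dim, noise_sd=embedding_noise_sd, seed=seed)
        ds.embeddings = emb
    return ds
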