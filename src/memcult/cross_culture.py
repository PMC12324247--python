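"""Cross-group consistency, median-split quadrants, and dimension comparisons.

Consistency between two groups' per-stimulus memorability scores is a
Pearson correlation over the common stimuli.  Each stimulus is then called
"memorable" within a group iff its score strictly exceeds that group's
median (configurable to >=), and the 2x2 of the two indicators defines four
quadrants: 1 = memorable in both groups, 2 = first group only, 3 = neither,
4 = second group only.  The two disagreement quadrants (2 vs 4) are compared
dimension-by-dimension with Welch one-tailed t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

TIE_POLICIES = ("strict_gt", "ge")


def cross_group_correlation(mem_a: pd.Series, mem_b: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation between two groups' scores on their common stimuli.

    Returns (r, two-sided p, n common stimuli).
    """
    common = mem_a.index.intersection(mem_b.index)
    n = len(common)
    if n < 3:
        raise ValidationError(f"need >= 3 common stimuli for a correlation, got {n}")
    res = stats.pearsonr(mem_a.loc[common], mem_b.loc[common])
    return float(res.statistic), float(res.pvalue), n


@dataclass
class QuadrantAssignment:
    """Median-split quadrant classification of the common stimuli."""

    quadrants: pd.Series  # stimulus -> quadrant in {1, 2, 3, 4}
    median_a: float
    median_b: float
    tie_policy: str

    @property
    def counts(self) -> dict[int, int]:
        c = self.quadrants.value_counts().to_dict()
        return {q: int(c.get(q, 0)) for q in (1, 2, 3, 4)}

    def stimuli_in(self, quadrant: int) -> list[str]:
        return sorted(self.quadrants.index[self.quadrants == quadrant])


def assign_quadrants(
    mem_a: pd.Series,
    mem_b: pd.Series,
    tie_policy: str = "strict_gt",
) -> QuadrantAssignment:
    """Classify stimuli by memorable/not-memorable status in each group.

    A stimulus is memorable within a group iff its score strictly exceeds
    (``strict_gt``, default) or equals-or-exceeds (``ge``) the group median
    over the common stimuli.  Quadrants: 1 both, 2 only group A, 3 neither,
    4 only group B.
    """
    if tie_policy not in TIE_POLICIES:
        raise ConfigurationError(f"tie_policy must be one of {TIE_POLICIES}, got {tie_policy!r}")
    common = mem_a.index.intersection(mem_b.index)
    if len(common) == 0:
        raise ValidationError("no common stimuli between the two score tables")
    a = mem_a.loc[common].astype(float)
    b = mem_b.loc[common].astype(float)
    med_a, med_b = float(a.median()), float(b.median())
    if tie_policy == "strict_gt":
        in_a, in_b = a > med_a, b > med_b
    else:
        in_a, in_b = a >= med_a, b >= med_b
    quad = pd.Series(3, index=common, dtype=int, name="quadrant")
    quad[in_a & in_b] = 1
    quad[in_a & ~in_b] = 2
    quad[~in_a & in_b] = 4
    return QuadrantAssignment(quadrants=quad, median_a=med_a, median_b=med_b, tie_policy=tie_policy)


def compare_dimensions(
    dim_scores: pd.DataFrame,
    stimuli_x: Sequence[str],
    stimuli_y: Sequence[str],
    alternative: str | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Welch two-sample t test per dimension between two stimulus sets.

    ``alternative``: "greater" tests mean(X) > mean(Y), "less" the reverse;
    None (default) takes the direction from the observed sign of the mean
    difference and flags the row ``post_hoc_direction``.  Dimensions where
    both sets have zero variance get t = 0, p = 1 and a ``zero_variance``
    flag.  Optional Benjamini-Hochberg adjusted p values (off by default,
    matching the raw one-tailed reporting convention).
    """
    stimuli_x, stimuli_y = list(stimuli_x), list(stimuli_y)
    if not stimuli_x or not stimuli_y:
        raise ValidationError("both stimulus sets must be non-empty")
    for name, s in (("X", stimuli_x), ("Y", stimuli_y)):
        missing = [st for st in s if st not in dim_scores.index]
        if missing:
            raise ValidationError(f"stimuli in set {name} missing from dimension table: {missing[:5]}")
    if alternative not in (None, "greater", "less"):
        raise ConfigurationError(f"alternative must be None, 'greater' or 'less', got {alternative!r}")
    X = dim_scores.loc[stimuli_x]
    Y = dim_scores.loc[stimuli_y]
    rows = []
    for dim in dim_scores.columns:
        x, y = X[dim].to_numpy(float), Y[dim].to_numpy(float)
        mx, my = float(np.mean(x)), float(np.mean(y))
        zero_var = x.var(ddof=0) == 0 and y.var(ddof=0) == 0
        post_hoc = alternative is None
        if post_hoc:
            direction = "greater" if mx >= my else "less"
        else:
            direction = alternative
        if zero_var:
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(x, y, equal_var=False, alternative=direction)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "dimension": dim,
                "mean_X": mx,
                "mean_Y": my,
                "t": t,
                "p_one_tailed": p,
                "direction": direction,
                "post_hoc_direction": post_hoc,
                "zero_variance": zero_var,
            }
        )
    out = pd.DataFrame(rows).set_index("dimension")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_fdr_bh"] = multipletests(out["p_one_tailed"], method="fdr_bh")[1]
    return out
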