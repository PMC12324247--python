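"""Culture-specific memorability and Life/Non-life regression models.

The component of one group's memorability not shared with the other group
is isolated by simple linear regression: regressing group A's scores on
group B's and keeping the residuals (and vice versa).  Dimensions are
categorized as life, nonlife or mixed by their labels (mixed dimensions
never enter a model).  For each category the k dimensions most correlated
(by |Pearson r|) with the target scores are used as predictors of a
multiple OLS regression, reported as R-squared, overall F, its p value and
the residual standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

CATEGORIES = ("life", "nonlife", "mixed")


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------


@dataclass
class CultureSpecificScores:
    """Residuals of each group's scores regressed on the other group's."""

    residual_a: pd.Series  # A regressed on B
    residual_b: pd.Series  # B regressed on A
    slope_a_on_b: float
    intercept_a_on_b: float
    slope_b_on_a: float
    intercept_b_on_a: float


def _simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, np.ndarray]:
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("predictor scores are constant; cannot residualize")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, y - (slope * x + intercept)


def residualize(mem_a: pd.Series, mem_b: pd.Series) -> CultureSpecificScores:
    """Culture-specific scores: OLS residuals in each direction.

    Residuals have exactly zero mean and zero correlation with their
    predictor (OLS orthogonality).
    """
    common = mem_a.index.intersection(mem_b.index)
    if len(common) < 3:
        raise ValidationError(f"need >= 3 common stimuli, got {len(common)}")
    a = mem_a.loc[common].to_numpy(dtype=float)
    b = mem_b.loc[common].to_numpy(dtype=float)
    s_ab, i_ab, res_a = _simple_ols(a, b)
    s_ba, i_ba, res_b = _simple_ols(b, a)
    return CultureSpecificScores(
        residual_a=pd.Series(res_a, index=common, name="residual_a"),
        residual_b=pd.Series(res_b, index=common, name="residual_b"),
        slope_a_on_b=s_ab,
        intercept_a_on_b=i_ab,
        slope_b_on_a=s_ba,
        intercept_b_on_a=i_ba,
    )


# ---------------------------------------------------------------------------
# categories and predictor selection
# ---------------------------------------------------------------------------


def categorize_dimensions(
    source,
    required_dimensions: Sequence[str] | None = None,
) -> dict[str, str]:
    """Load and validate a dimension -> {life, nonlife, mixed} map.

    ``source`` is a TSV path (columns ``dimension, category``), a DataFrame
    of the same shape, or an existing mapping.  If ``required_dimensions``
    is given, every one of them must be covered.
    """
    if isinstance(source, Mapping):
        cat = dict(source)
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
        if not {"dimension", "category"} <= set(df.columns):
            raise ValidationError("category table needs columns 'dimension' and 'category'")
        cat = dict(zip(df["dimension"], df["category"]))
    bad = {d: c for d, c in cat.items() if c not in CATEGORIES}
    if bad:
        raise ValidationError(f"invalid categories (must be one of {CATEGORIES}): {bad}")
    if required_dimensions is not None:
        missing = [d for d in required_dimensions if d not in cat]
        if missing:
            raise ValidationError(f"dimensions without a category: {missing}")
    return cat


def select_top_correlated(
    dim_scores: pd.DataFrame,
    target_scores: pd.Series,
    category_map: Mapping[str, str],
    category: str,
    k: int = 6,
) -> list[str]:
    """The k dimensions of a category most |Pearson r|-correlated with the target.

    Deterministic: ties in |r| are broken by dimension name.
    """
    categorize_dimensions(category_map, required_dimensions=dim_scores.columns)
    dims = [d for d in dim_scores.columns if category_map[d] == category]
    if len(dims) < k:
        raise ValidationError(
            f"category {category!r} has {len(dims)} dimensions, fewer than k={k}"
        )
    common = dim_scores.index.intersection(target_scores.index)
    if len(common) < 3:
        raise ValidationError(f"need >= 3 stimuli with both scores, got {len(common)}")
    t = target_scores.loc[common].to_numpy(dtype=float)
    abs_r = {}
    for d in dims:
        x = dim_scores.loc[common, d].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(t) == 0:
            abs_r[d] = 0.0
        else:
            abs_r[d] = abs(float(np.corrcoef(x, t)[0, 1]))
    ranked = sorted(dims, key=lambda d: (-abs_r[d], d))
    return ranked[:k]


# ---------------------------------------------------------------------------
# category regression models
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Summary of one fitted multiple OLS regression."""

    r2: float
    f: float
    p: float
    residual_se: float
    coefficients: pd.DataFrame  # index: const + predictors; columns: coef, se
    predictors: list[str]
    n: int

    def as_row(self) -> dict:
        return {"r2": self.r2, "f": self.f, "p": self.p, "error": self.residual_se}


def fit_category_model(
    target: pd.Series,
    dim_scores: pd.DataFrame,
    predictors: Sequence[str],
) -> RegressionResult:
    """Multiple OLS of the target on the selected dimensions (with intercept).

    Residual standard error is sqrt(SSR / (n - k - 1)).
    """
    predictors = list(predictors)
    missing = [p for p in predictors if p not in dim_scores.columns]
    if missing:
        raise ValidationError(f"predictors missing from dimension table: {missing}")
    common = dim_scores.index.intersection(target.index)
    n, k = len(common), len(predictors)
    if n <= k + 1:
        raise ValidationError(f"n={n} stimuli insufficient for {k} predictors")
    X = dim_scores.loc[common, predictors].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = [
            p for i, p in enumerate(predictors)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == np.linalg.matrix_rank(design)
        ]
        raise ValidationError(f"design matrix is rank-deficient; collinear predictors: {collinear}")
    y = target.loc[common].to_numpy(dtype=float)
    fit = sm.OLS(y, design).fit()
    coef = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse}, index=["const"] + predictors
    )
    return RegressionResult(
        r2=float(fit.rsquared),
        f=float(fit.fvalue),
        p=float(fit.f_pvalue),
        residual_se=float(np.sqrt(fit.ssr / fit.df_resid)),
        coefficients=coef,
        predictors=predictors,
        n=n,
    )


def run_culture_models(
    mem_a: pd.Series,
    mem_b: pd.Series,
    dim_scores: pd.DataFrame,
    category_map: Mapping[str, str],
    k: int = 6,
    group_names: tuple[str, str] = ("A", "B"),
    selection_target: str = "residual",
) -> pd.DataFrame:
    """Fit the Life and Non-life models of each group's culture-specific scores.

    ``selection_target`` chooses whether the top-k predictors are ranked by
    correlation with the residual (culture-specific) scores, the model's
    dependent variable (default), or with the raw memorability scores.
    Returns a tidy table ``group, model, r2, f, p, error, predictors``.
    """
    if selection_target not in ("residual", "raw"):
        raise ValidationError(f"selection_target must be 'residual' or 'raw', got {selection_target!r}")
    css = residualize(mem_a, mem_b)
    rows = []
    for gname, resid, raw in (
        (group_names[0], css.residual_a, mem_a),
        (group_names[1], css.residual_b, mem_b),
    ):
        sel_target = resid if selection_target == "residual" else raw
        for category, label in (("life", "Life"), ("nonlife", "Non-life")):
            preds = select_top_correlated(dim_scores, sel_target, category_map, category, k=k)
            res = fit_category_model(resid, dim_scores, preds)
            rows.append(
                {"group": gname, "model": label, **res.as_row(), "predictors": ",".join(preds)}
            )
    out = pd.DataFrame(rows)
    out.attrs["selection_target"] = selection_target
    return out
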