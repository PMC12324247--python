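"""Elastic-net transfer of object-dimension scores from stimulus embeddings.

One elastic-net regression per dimension maps a numeric stimulus-embedding
matrix to that dimension's reference scores.  Penalty strength and mixing
parameter are chosen per dimension by k-fold cross-validation maximizing
the mean validation Pearson correlation (the metric transfer quality is
reported in), and the winning model is refit on all data.  Embeddings are
standardized per feature using training-fold statistics only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

from . import _rng
from .errors import ConfigurationError, ValidationError

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
DEFAULT_ALPHAS = tuple(np.logspace(-4, 1, 7))
R_THRESHOLDS = (0.7, 0.8, 0.9)


@dataclass
class DimensionModel:
    """A fitted per-dimension linear readout in the original embedding space."""

    name: str
    weights: np.ndarray
    intercept: float
    alpha: float
    l1_ratio: float
    cv_r: float
    train_r: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.weights):
            raise ValidationError(
                f"embedding width {X.shape[1]} != model width {len(self.weights)} "
                f"for dimension {self.name!r}"
            )
        return X @ self.weights + self.intercept


@dataclass
class TransferReport:
    """Held-out transfer accuracy: per-dimension Pearson r and threshold counts."""

    per_dimension_r: pd.Series
    thresholds: tuple[float, ...] = R_THRESHOLDS
    counts: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            r = self.per_dimension_r
            self.counts = {t: int((r > t).sum()) for t in self.thresholds}


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0 when either input is (numerically) constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt(np.sum(da**2)), np.sqrt(np.sum(db**2))
    if na == 0 or nb == 0 or not np.isfinite(na) or not np.isfinite(nb):
        return 0.0
    return float(np.clip(np.sum(da * db) / (na * nb), -1.0, 1.0))


def _make_regressor(alpha: float, l1_ratio: float):
    # alpha == 0 is ordinary least squares; coordinate descent is unreliable there
    if alpha == 0:
        return LinearRegression()
    return ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)


class ElasticNetDimensionTransfer(BaseEstimator):
    """Per-dimension elastic-net mapping from embeddings to dimension scores.

    Parameters
    ----------
    alphas, l1_ratios : sequences forming the hyperparameter grid (the grid
        is searched in ``for l1_ratio: for alpha`` order; ties in mean CV r
        keep the first-visited point).
    n_folds : cross-validation folds (default 10).
    random_state : seed controlling the fold shuffle.

    Attributes (after fit)
    ----------------------
    models_ : list of DimensionModel, one per non-constant dimension.
    cv_r_, train_r_ : dict dimension -> chosen mean CV r / full-data train r.
    dimension_names_, n_features_in_
    """

    def __init__(
        self,
        alphas: Sequence[float] = DEFAULT_ALPHAS,
        l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
        n_folds: int = 10,
        random_state: int | None = None,
    ):
        self.alphas = alphas
        self.l1_ratios = l1_ratios
        self.n_folds = n_folds
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _as_matrix(X) -> tuple[np.ndarray, list | None]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.index)
        return np.asarray(X, dtype=float), None

    def fit(self, X, Y, dimension_names: Sequence[str] | None = None):
        """Fit one model per dimension (columns of ``Y``) with CV-chosen penalties."""
        Xm, _ = self._as_matrix(X)
        if isinstance(Y, pd.DataFrame):
            names = list(Y.columns)
            Ym = Y.to_numpy(dtype=float)
        else:
            Ym = np.asarray(Y, dtype=float)
            if Ym.ndim == 1:
                Ym = Ym[:, None]
            names = list(dimension_names) if dimension_names is not None else [
                f"dim{j}" for j in range(Ym.shape[1])
            ]
        if Xm.shape[0] != Ym.shape[0]:
            raise ValidationError(
                f"embeddings have {Xm.shape[0]} rows but scores have {Ym.shape[0]}"
            )
        n = Xm.shape[0]
        if n < self.n_folds:
            raise ConfigurationError(f"n={n} samples < n_folds={self.n_folds}")

        kf = KFold(
            n_splits=self.n_folds,
            shuffle=True,
            random_state=_rng.derived_state(self.random_state, _rng.KEY_CV_FOLDS),
        )
        splits = list(kf.split(Xm))
        # per-fold standardization is shared by every dimension and grid point
        scaled = []
        for tr, va in splits:
            mu = Xm[tr].mean(axis=0)
            sd = Xm[tr].std(axis=0)
            sd[sd == 0] = 1.0
            scaled.append(((Xm[tr] - mu) / sd, (Xm[va] - mu) / sd, tr, va))

        grid = [(l1, a) for l1 in self.l1_ratios for a in self.alphas]
        self.models_ = []
        self.cv_r_ = {}
        self.train_r_ = {}
        mu_all = Xm.mean(axis=0)
        sd_all = Xm.std(axis=0)
        sd_all[sd_all == 0] = 1.0
        Xs_all = (Xm - mu_all) / sd_all
        for j, name in enumerate(names):
            y = Ym[:, j]
            if np.std(y) == 0:
                warnings.warn(f"dimension {name!r} is constant; skipped", stacklevel=2)
                continue
            best = None
            for l1, a in grid:
                rs = []
                for Xtr, Xva, tr, va in scaled:
                    reg = _make_regressor(a, l1)
                    reg.fit(Xtr, y[tr])
                    rs.append(_safe_pearson(reg.predict(Xva), y[va]))
                mean_r = float(np.mean(rs))
                if best is None or mean_r > best[0]:
                    best = (mean_r, l1, a)
            mean_r, l1, a = best
            reg = _make_regressor(a, l1)
            reg.fit(Xs_all, y)
            w_std = np.asarray(reg.coef_, dtype=float).ravel()
            w = w_std / sd_all
            b = float(reg.intercept_) - float(np.sum(w_std * mu_all / sd_all))
            train_r = _safe_pearson(Xm @ w + b, y)
            self.models_.append(
                DimensionModel(
                    name=name, weights=w, intercept=b, alpha=a, l1_ratio=l1,
                    cv_r=mean_r, train_r=train_r,
                )
            )
            self.cv_r_[name] = mean_r
            self.train_r_[name] = train_r
        self.dimension_names_ = [m.name for m in self.models_]
        self.n_features_in_ = Xm.shape[1]
        return self

    def predict(self, X) -> pd.DataFrame:
        """Predicted dimension scores for new embeddings (affine, no clipping)."""
        if not hasattr(self, "models_"):
            raise ValidationError("estimator is not fitted")
        Xm, index = self._as_matrix(X)
        return predict_dimensions(self.models_, Xm, index=index)

    def evaluate(self, X_heldout, Y_heldout) -> TransferReport:
        if not hasattr(self, "models_"):
            raise ValidationError("estimator is not fitted")
        return evaluate_transfer(self.models_, X_heldout, Y_heldout)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_dimension_models(
    embeddings,
    dim_scores,
    n_folds: int = 10,
    penalty_grid: dict | None = None,
    seed: int | None = None,
) -> list[DimensionModel]:
    """Fit per-dimension elastic nets; thin wrapper over ElasticNetDimensionTransfer."""
    grid = penalty_grid or {}
    est = ElasticNetDimensionTransfer(
        alphas=tuple(grid.get("alphas", DEFAULT_ALPHAS)),
        l1_ratios=tuple(grid.get("l1_ratios", DEFAULT_L1_RATIOS)),
        n_folds=n_folds,
        random_state=seed,
    )
    est.fit(embeddings, dim_scores)
    return est.models_


def predict_dimensions(
    models: Sequence[DimensionModel],
    embeddings,
    index: Sequence | None = None,
) -> pd.DataFrame:
    """Linear per-dimension predictions for an embedding matrix."""
    if isinstance(embeddings, pd.DataFrame):
        index = list(embeddings.index)
        embeddings = embeddings.to_numpy(dtype=float)
    X = np.asarray(embeddings, dtype=float)
    out = {m.name: m.predict(X) for m in models}
    return pd.DataFrame(out, index=index if index is not None else range(X.shape[0]))


def evaluate_transfer(models: Sequence[DimensionModel], embeddings_heldout, scores_heldout) -> TransferReport:
    """Held-out Pearson r per dimension plus counts above r thresholds.

    The caller guarantees the held-out stimuli are disjoint from training.
    """
    if isinstance(scores_heldout, pd.DataFrame):
        truth = scores_heldout
    else:
        truth = pd.DataFrame(np.asarray(scores_heldout, dtype=float), columns=[m.name for m in models])
    if truth.shape[0] < 3:
        raise ValidationError(f"need >= 3 held-out stimuli, got {truth.shape[0]}")
    preds = predict_dimensions(models, embeddings_heldout)
    rs = {}
    for m in models:
        rs[m.name] = _safe_pearson(preds[m.name].to_numpy(), truth[m.name].to_numpy(dtype=float))
    return TransferReport(per_dimension_r=pd.Series(rs, name="r"))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def models_to_json(models: Sequence[DimensionModel], path) -> None:
    payload = [
        {
            "name": m.name,
            "weights": m.weights.tolist(),
            "intercept": m.intercept,
            "alpha": m.alpha,
            "l1_ratio": m.l1_ratio,
            "cv_r": m.cv_r,
            "train_r": m.train_r,
        }
        for m in models
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def models_from_json(path) -> list[DimensionModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        DimensionModel(
            name=m["name"],
            weights=np.asarray(m["weights"], dtype=float),
            intercept=float(m["intercept"]),
            alpha=float(m["alpha"]),
            l1_ratio=float(m["l1_ratio"]),
            cv_r=float(m["cv_r"]),
            train_r=float(m.get("train_r", float("nan"))),
        )
        for m in payload
    ]
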