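"""Residualization and Life/Non-life regression-model contracts."""

import numpy as np
import pandas as pd
import pytest

from memcult import synthetic as syn
from memcult.errors import ValidationError
from memcult.models import (
    categorize_dimensions,
    fit_category_model,
    residualize,
    run_culture_models,
    select_top_correlated,
)


def series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)


class TestResidualize:
    def test_exact_linear_relation_gives_zero_residuals(self):
        a = series([1, 2, 3, 4, 5])
        b = 2 * a + 1
        css = residualize(a, b)
        np.testing.assert_allclose(css.residual_b.to_numpy(), 0.0, atol=1e-12)
        assert css.slope_b_on_a == pytest.approx(2.0)
        assert css.intercept_b_on_a == pytest.approx(1.0)

    def test_orthogonality(self):
        rng = np.random.default_rng(0)
        a = series(rng.normal(size=200))
        b = series(0.5 * a.to_numpy() + rng.normal(size=200))
        css = residualize(a, b)
        scale = np.abs(css.residual_b).max()
        assert abs(css.residual_b.mean()) < 1e-10 * scale
        assert abs(np.corrcoef(css.residual_b, a)[0, 1]) < 1e-10
        assert abs(np.corrcoef(css.residual_a, b)[0, 1]) < 1e-10

    def test_independent_predictor_keeps_total_variance(self):
        rng = np.random.default_rng(1)
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = series(rng.normal(size=300))
            b = series(rng.normal(size=300))
            css = residualize(a, b)
            ratios.append(css.residual_b.var() / b.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            residualize(series([1, 2, 3, 4]), series([2, 2, 2, 2]))
        # the reverse direction fails too (constant on either side)
        with pytest.raises(ValidationError, match="constant"):
            residualize(series([2, 2, 2, 2]), series([1, 2, 3, 4]))


class TestCategories:
    def test_bundled_map_matches_label_semantics(self):
        _, cats = syn.load_default_dimension_metadata()
        assert cats["Animal/organic"] == "life"
        assert cats["Arms/skin"] == "life"
        assert cats["Metal/artificial"] == "nonlife"
        assert cats["Fire/heat"] == "nonlife"
        assert cats["Sky/flying"] == "mixed"
        assert len(cats) == 49

    def test_uncovered_dimension_named_in_error(self):
        with pytest.raises(ValidationError, match="Mystery/dim"):
            categorize_dimensions({"a": "life"}, required_dimensions=["a", "Mystery/dim"])

    def test_invalid_category_rejected(self):
        with pytest.raises(ValidationError, match="invalid"):
            categorize_dimensions({"a": "alive"})

    def test_tsv_roundtrip(self, tmp_path):
        from memcult.io import write_categories_tsv

        path = tmp_path / "cats.tsv"
        write_categories_tsv({"a": "life", "b": "mixed"}, path)
        assert categorize_dimensions(path) == {"a": "life", "b": "mixed"}


class TestSelectTopCorrelated:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(
            {f"L{j}": rng.normal(size=n) for j in range(4)}
            | {f"N{j}": rng.normal(size=n) for j in range(3)},
            index=idx,
        )
        cats = {c: ("life" if c.startswith("L") else "nonlife") for c in df.columns}
        return df, cats

    def test_exact_match_ranks_first(self):
        df, cats = self._table()
        target = df["L2"].copy()
        top = select_top_correlated(df, target, cats, "life", k=2)
        assert top[0] == "L2"

    def test_negative_correlation_counts_by_magnitude(self):
        df, cats = self._table()
        target = -df["L1"]
        assert select_top_correlated(df, target, cats, "life", k=1) == ["L1"]

    def test_whole_category_when_k_equals_size(self):
        df, cats = self._table()
        target = series(np.arange(50))
        assert sorted(select_top_correlated(df, target, cats, "nonlife", k=3)) == ["N0", "N1", "N2"]

    def test_k_too_large(self):
        df, cats = self._table()
        with pytest.raises(ValidationError, match="fewer than k"):
            select_top_correlated(df, df["L0"], cats, "nonlife", k=4)

    def test_null_target_still_returns_k(self):
        df, cats = self._table(seed=3)
        rng = np.random.default_rng(99)
        target = pd.Series(rng.normal(size=50), index=df.index)
        assert len(select_top_correlated(df, target, cats, "life", k=3)) == 3


class TestFitCategoryModel:
    def test_exact_linear_combination(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"d{j}" for j in range(6)],
                          index=[f"s{i}" for i in range(40)])
        target = df @ np.arange(1.0, 7.0) + 3.0
        res = fit_category_model(target, df, list(df.columns))
        assert res.r2 == pytest.approx(1.0)
        assert res.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_f_statistic_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"),
                          index=[f"s{i}" for i in range(100)])
        target = pd.Series(df["a"] * 0.5 + rng.normal(size=100), index=df.index)
        res = fit_category_model(target, df, list("abcd"))
        n, k = res.n, len(res.predictors)
        f_closed = (res.r2 / k) / ((1 - res.r2) / (n - k - 1))
        assert res.f == pytest.approx(f_closed, rel=1e-10)

    def test_r2_equals_correlation_matrix_closed_form(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("xyz"),
                          index=[f"s{i}" for i in range(80)])
        target = pd.Series(df["x"] - 0.3 * df["y"] + rng.normal(size=80), index=df.index)
        res = fit_category_model(target, df, list("xyz"))
        # R^2 = r_xy' Rxx^-1 r_xy from the joint correlation matrix
        all_vars = np.column_stack([target.to_numpy()] + [df[c].to_numpy() for c in "xyz"])
        C = np.corrcoef(all_vars, rowvar=False)
        r_xy = C[1:, 0]
        closed = float(r_xy @ np.linalg.solve(C[1:, 1:], r_xy))
        assert res.r2 == pytest.approx(closed, rel=1e-10)

    def test_rank_deficiency_names_collinear_predictors(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=30)}, index=[f"s{i}" for i in range(30)])
        df["b"] = 2 * df["a"]
        df["c"] = rng.normal(size=30)
        target = pd.Series(rng.normal(size=30), index=df.index)
        with pytest.raises(ValidationError, match="collinear"):
            fit_category_model(target, df, ["a", "b", "c"])

    def test_insufficient_n(self):
        df = pd.DataFrame(np.eye(4), columns=list("abcd"), index=list("wxyz"))
        target = pd.Series([1.0, 2, 3, 4], index=list("wxyz"))
        with pytest.raises(ValidationError, match="insufficient"):
            fit_category_model(target, df, list("abcd"))


class TestRunCultureModels:
    def test_planted_life_effect_detected_in_first_group(self, small_ds):
        import memcult

        tab = memcult.memorability_table(small_ds.trials)
        wide = tab.pivot(index="stimulus", columns="group", values="memorability")
        out = run_culture_models(
            wide["CN"], wide["US"], small_ds.dimensions.scores,
            small_ds.dimensions.categories, k=3, group_names=("CN", "US"),
        )
        r2 = out.set_index(["group", "model"])["r2"]
        assert r2[("CN", "Life")] > r2[("US", "Life")]
        assert set(out["model"]) == {"Life", "Non-life"}
        assert (out["r2"] >= 0).all() and (out["r2"] <= 1).all()

    def test_mixed_dimensions_never_used(self, default_ds):
        import memcult

        tab = memcult.memorability_table(default_ds.trials)
        wide = tab.pivot(index="stimulus", columns="group", values="memorability")
        out = run_culture_models(
            wide["CN"], wide["US"], default_ds.dimensions.scores,
            default_ds.dimensions.categories, k=6, group_names=("CN", "US"),
        )
        mixed = {d for d, c in default_ds.dimensions.categories.items() if c == "mixed"}
        assert mixed  # the bundled map does contain mixed dimensions
        for preds in out["predictors"]:
            assert not (set(preds.split(",")) & mixed)
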