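"""Generator contracts: balanced design, determinism, and planted-effect limits."""

import numpy as np
import pandas as pd
import pytest

import memcult
from memcult import synthetic as syn
from memcult.errors import ConfigurationError, ValidationError


def _names(n):
    names, cats = syn.load_default_dimension_metadata()
    return names[:n], {d: cats[d] for d in names[:n]}


class TestGenerateDesign:
    def test_study_scale_counterbalancing(self):
        plan = syn.generate_design(120, 600, 4, seed=1)
        old_counts = {k: 0 for k in range(4)}
        new_counts = {k: 0 for k in range(4)}
        for old, new in plan.participant_assignment.values():
            assert old != new
            old_counts[old] += 1
            new_counts[new] += 1
        assert all(v == 30 for v in old_counts.values())
        assert all(v == 30 for v in new_counts.values())
        sizes = pd.Series(plan.subset_assignment).value_counts()
        assert (sizes == 150).all()

    def test_smallest_balanced_design(self):
        plan = syn.generate_design(2, 4, 2, seed=0)
        assert len(plan.stimuli_in_subset(0)) == 2
        pairs = sorted(plan.participant_assignment.values())
        assert pairs == [(0, 1), (1, 0)]

    @pytest.mark.parametrize(
        "args,fragment",
        [
            ((120, 601, 4), "n_stimuli"),
            ((121, 600, 4), "n_participants_per_group"),
            ((120, 600, 1), "n_subsets"),
        ],
    )
    def test_divisibility_errors_name_the_quantity(self, args, fragment):
        with pytest.raises(ConfigurationError, match=fragment):
            syn.generate_design(*args, seed=1)

    def test_seed_determinism(self):
        a = syn.generate_design(12, 40, 2, seed=5)
        b = syn.generate_design(12, 40, 2, seed=5)
        assert a.subset_assignment == b.subset_assignment
        assert a.participant_assignment == b.participant_assignment
        c = syn.generate_design(12, 40, 2, seed=6)
        assert c.subset_assignment != a.subset_assignment


class TestDimensionSpace:
    def test_nonnegative_with_variance(self):
        names, cats = _names(10)
        tab = syn.generate_dimension_space(50, 10, names, cats, sparsity=0.7, seed=2)
        assert (tab.scores.to_numpy() >= 0).all()
        assert (tab.scores.var(axis=0) > 0).all()
        assert tab.dimension_names == names

    def test_dense_small_table(self):
        tab = syn.generate_dimension_space(10, 2, ["a", "b"], ["life", "nonlife"], 0.0, seed=0)
        assert tab.scores.shape == (10, 2)
        assert (tab.scores.to_numpy() > 0).all()

    def test_full_sparsity_rejected(self):
        with pytest.raises(ConfigurationError, match="sparsity"):
            syn.generate_dimension_space(10, 2, ["a", "b"], ["life", "life"], 1.0, seed=0)

    def test_name_category_mismatch(self):
        with pytest.raises(ConfigurationError):
            syn.generate_dimension_space(10, 2, ["a", "b"], ["life"], 0.0, seed=0)
        with pytest.raises(ConfigurationError):
            syn.generate_dimension_space(10, 3, ["a", "b"], ["life", "life"], 0.0, seed=0)


class TestEmbeddings:
    def test_noiseless_exactly_linear(self):
        names, cats = _names(5)
        tab = syn.generate_dimension_space(30, 5, names, cats, 0.2, seed=3)
        emb, M = syn.generate_embeddings(tab, 12, noise_sd=0.0, seed=3)
        np.testing.assert_allclose(emb.to_numpy() @ M, tab.scores.to_numpy(), atol=1e-8)

    def test_least_squares_refit_recovers_map(self):
        # normal-equations oracle: with noise, OLS from embeddings to scores
        # should land close to the true map
        names, cats = _names(5)
        tab = syn.generate_dimension_space(600, 5, names, cats, 0.2, seed=4)
        emb, M = syn.generate_embeddings(tab, 8, noise_sd=0.1, seed=4)
        Z, X = emb.to_numpy(), tab.scores.to_numpy()
        M_hat = np.linalg.solve(Z.T @ Z, Z.T @ X)
        assert np.abs(M_hat - M).max() < 0.05

    def test_width_error(self):
        names, cats = _names(5)
        tab = syn.generate_dimension_space(30, 5, names, cats, 0.2, seed=3)
        with pytest.raises(ConfigurationError, match="embed_dim"):
            syn.generate_embeddings(tab, 4, seed=0)


class TestSimulateTrials:
    def test_trial_counts_and_response_range(self, small_ds):
        per = small_ds.trials.groupby(["participant", "phase"]).size().unstack()
        assert (per["encoding"] == 40).all()
        assert (per["recognition"] == 80).all()
        assert small_ds.trials["response"].between(1, 6).all()

    def test_counterbalanced_old_new_per_stimulus(self, small_ds):
        rec = small_ds.trials[small_ds.trials.phase == "recognition"]
        counts = rec.groupby(["group", "stimulus", "status"]).size()
        assert (counts == 6).all()  # 12 participants / 2 subsets

    def test_noiseless_separation(self):
        # huge offsets, no noise: every old item is answered "definitely yes"
        # (reverse-coded 6), every new item "definitely no" (reverse-coded 1)
        names, cats = _names(3)
        design = syn.generate_design(2, 4, 2, seed=0)
        dims = syn.generate_dimension_space(4, 3, names, cats, 0.0, seed=0)
        cfg = syn.EffectConfig(
            shared_sd=0.0, group_sd=0.0, trial_sd=0.0, old_offset=100.0, new_offset=-100.0,
        )
        ds = syn.simulate_trials(design, dims, cfg, seed=0)
        rec = ds.trials[ds.trials.phase == "recognition"]
        coded = 7 - rec["response"]
        assert (coded[rec.status == "old"] == 6).all()
        assert (coded[rec.status == "new"] == 1).all()

    def test_empirical_score_tracks_true_latent(self, default_ds):
        tab = memcult.memorability_table(default_ds.trials)
        wide = tab.pivot(index="stimulus", columns="group", values="memorability")
        for g in default_ds.group_ids:
            r = np.corrcoef(wide[g], default_ds.true_memorability[g].loc[wide.index])[0, 1]
            assert r > 0.9

    def test_shared_only_limit_gives_near_perfect_cross_group_r(self):
        # no group-specific structure and vanishing trial noise: the two
        # groups' scores converge to the same shared latent
        names, cats = _names(4)
        design = syn.generate_design(12, 80, 2, seed=9)
        dims = syn.generate_dimension_space(80, 4, names, cats, 0.3, seed=9)
        cfg = syn.EffectConfig(shared_sd=0.5, group_sd=0.0, trial_sd=0.01)
        ds = syn.simulate_trials(design, dims, cfg, seed=9)
        tab = memcult.memorability_table(ds.trials)
        wide = tab.pivot(index="stimulus", columns="group", values="memorability")
        r, _, _ = memcult.cross_group_correlation(wide["CN"], wide["US"])
        assert r > 0.95

    def test_seed_determinism_byte_identical(self, small_ds):
        names, cats = _names(20)
        design = syn.generate_design(12, 80, 2, seed=7)
        dims = syn.generate_dimension_space(80, 20, names, cats, 0.5, seed=7)
        eff = syn.plant_cultural_effects(
            dims, n_shared=6, n_life=4, n_nonlife=3, life_strength=0.4, nonlife_strength=0.12, seed=7
        )
        again = syn.simulate_trials(design, dims, eff, seed=7)
        pd.testing.assert_frame_equal(again.trials, small_ds.trials)
        pd.testing.assert_frame_equal(again.true_memorability, small_ds.true_memorability)

    def test_old_offset_monotonicity(self):
        # same seed, larger old offset: no stimulus's score can decrease
        names, cats = _names(4)
        design = syn.generate_design(4, 8, 2, seed=3)
        dims = syn.generate_dimension_space(8, 4, names, cats, 0.3, seed=3)

        def scores(old_offset):
            cfg = syn.EffectConfig(old_offset=old_offset)
            ds = syn.simulate_trials(design, dims, cfg, seed=3)
            tab = memcult.memorability_table(ds.trials)
            return tab.set_index(["stimulus", "group"])["memorability"]

        lo, hi = scores(0.5), scores(1.5)
        assert (hi >= lo).all()

    def test_weight_length_mismatch(self):
        names, cats = _names(4)
        design = syn.generate_design(2, 4, 2, seed=0)
        dims = syn.generate_dimension_space(4, 4, names, cats, 0.0, seed=0)
        with pytest.raises(ConfigurationError, match="shared_weights"):
            syn.simulate_trials(design, dims, syn.EffectConfig(shared_weights=np.ones(3)), seed=0)
        with pytest.raises(ConfigurationError, match="thresholds"):
            syn.simulate_trials(
                design, dims, syn.EffectConfig(thresholds=(0, 0, 1, 2, 3)), seed=0
            )

    def test_design_dimension_stimulus_mismatch(self):
        names, cats = _names(2)
        design = syn.generate_design(2, 8, 2, seed=0)
        dims = syn.generate_dimension_space(4, 2, names, cats, 0.0, seed=0)
        with pytest.raises(ValidationError, match="missing from dimension table"):
            syn.simulate_trials(design, dims, seed=0)
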