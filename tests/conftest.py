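import pandas as pd
import pytest

from memcult import synthetic as syn


@pytest.fixture(scope="session")
def default_ds():
    """Full default-scale study: 120+120 participants, 600 stimuli, 49 dims."""
    return syn.default_dataset(seed=11)


@pytest.fixture(scope="session")
def small_ds():
    """Reduced study (12+12 participants, 80 stimuli, 20 dims) for fast tests."""
    names, cats = syn.load_default_dimension_metadata()
    nm = names[:20]
    design = syn.generate_design(12, 80, 2, seed=7)
    dims = syn.generate_dimension_space(80, 20, nm, {n: cats[n] for n in nm}, 0.5, seed=7)
    # stronger planted effects than the full-scale defaults: at 80 stimuli the
    # regression models need a larger signal for reliable recovery
    eff = syn.plant_cultural_effects(
        dims, n_shared=6, n_life=4, n_nonlife=3, life_strength=0.4, nonlife_strength=0.12, seed=7
    )
    return syn.simulate_trials(design, dims, eff, seed=7)


def make_trials(rows):
    """Hand-built trial table from (participant, group, phase, stimulus, status, response)."""
    return pd.DataFrame(
        rows, columns=["participant", "group", "phase", "stimulus", "status", "response"]
    )


@pytest.fixture
def hand_trials():
    """One group, one stimulus: old raw {3,2,1}, new raw {6,5,4} plus encoding {1,2,3}."""
    rows = []
    for i, r in enumerate([3, 2, 1]):
        rows.append((f"p{i}", "CN", "recognition", "s1", "old", r))
    for i, r in enumerate([6, 5, 4]):
        rows.append((f"p{i}", "CN", "recognition", "s1", "new", r))
    for i, r in enumerate([1, 2, 3]):
        rows.append((f"p{i}", "CN", "encoding", "s1", "na", r))
    return make_trials(rows)
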