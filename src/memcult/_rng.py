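"""Deterministic random-stream derivation.

All stochastic operations take one integer seed; independent substreams are
derived from it with fixed keys so that adding a new consumer never perturbs
existing ones.
"""

from __future__ import annotations

import numpy as np

# fixed substream keys
KEY_DESIGN = 0
KEY_DIMENSIONS = 1
KEY_EMBEDDINGS = 2
KEY_SHARED_LATENT = 10
KEY_GROUP_LATENT = 20  # + group index
KEY_TRIAL_NOISE = 40  # + group index
KEY_ENCODING_NOISE = 60  # + group index
KEY_EFFECTS = 80
KEY_CV_FOLDS = 90
KEY_RFE_FOLDS = 100  # + repeat index


def substream(seed: int | None, key: int) -> np.random.Generator:
    """Generator for substream ``key`` of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def derived_state(seed: int | None, key: int) -> int:
    """A 31-bit integer usable as an sklearn ``random_state``."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))
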