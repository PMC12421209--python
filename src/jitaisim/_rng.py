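"""Deterministic RNG stream derivation.

One master seed drives the whole pipeline.  Every stage and every person gets
an independent child generator derived via ``numpy.random.SeedSequence`` spawn
keys, so regenerating any subset of the cohort (or any single stage)
reproduces exactly the same draws regardless of what else ran.
"""

from __future__ import annotations

import numpy as np

# Stage tags used as the first spawn-key element.
COHORT_TAG = 0
STREAM_TAG = 1
TRIAL_TAG = 2
EFFECTS_TAG = 3
EVENING_TAG = 4


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for stage/person ``key`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))
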