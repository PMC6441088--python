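"""Counter-based child-seed derivation.

One master seed expands into independent per-stage streams via
:class:`numpy.random.SeedSequence` spawn keys, so adding a stage never
perturbs the randomness of the others.
"""

from __future__ import annotations

import numpy as np

# Fixed stage counters; append only, never renumber.
_STAGES = {
    "archetypes": 0,
    "weights": 1,
    "background": 2,
    "noise": 3,
    "null_maps": 4,
    "connectivity": 5,
    "permutation": 6,
    "pareto_null": 7,
    "pool_sampling": 8,
    "misc": 9,
}


def stage_seed_sequence(master_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Return the SeedSequence for a named stage (optionally sub-indexed)."""
    try:
        key = _STAGES[stage]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unknown seed stage {stage!r}; known: {sorted(_STAGES)}")
    return np.random.SeedSequence(int(master_seed), spawn_key=(key, int(index)))


def stage_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for a named stage of the pipeline."""
    return np.random.default_rng(stage_seed_sequence(master_seed, stage, index))


def child_int_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """A plain integer child seed below 2**31 (for APIs that want an int)."""
    return int(stage_seed_sequence(master_seed, stage, index).generate_state(1)[0] % (2**31))
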