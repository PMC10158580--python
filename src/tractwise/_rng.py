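"""Seed management.

One global integer seed expands into independent per-stage child seeds
through :func:`child_rng`. The rule is fixed: stage ``name`` is mapped to a
stable integer code and the child generator is built from
``SeedSequence((seed, code, index))``. Rerunning any one stage with the same
global seed therefore reproduces it exactly, independent of whether the
other stages ran.
"""

from __future__ import annotations

import numpy as np

# Stable stage codes; append only, never renumber.
_STAGE_CODES = {
    "behavior": 0,
    "profiles": 1,
    "permutation": 2,
    "bootstrap": 3,
    "availability": 4,
    "missingness": 5,
}


def child_seed_sequence(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    if stage not in _STAGE_CODES:
        raise KeyError(f"unknown rng stage {stage!r}; known: {sorted(_STAGE_CODES)}")
    if not 0 <= int(seed) < 2**63:
        raise ValueError("seed must be a non-negative integer below 2**63")
    return np.random.SeedSequence((int(seed), _STAGE_CODES[stage], int(index)))


def child_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for one pipeline stage derived from the global seed."""
    return np.random.default_rng(child_seed_sequence(seed, stage, index))
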