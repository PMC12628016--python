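"""Deterministic master-seed -> per-stage child-seed derivation.

Each pipeline stage draws its randomness from a child seed derived from the
master seed and a fixed stage index, so adding a stage never perturbs the
random streams of earlier stages.
"""

from __future__ import annotations

import numpy as np

# Fixed, append-only registry of stage indices.
STAGE_IDS = {
    "simulate": 0,
    "score": 1,
    "mvt": 2,
    "cpm": 3,
    "cpm_permutation": 4,
    "mediate": 5,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Return a deterministic 31-bit child seed for a named pipeline stage."""
    if stage not in STAGE_IDS:
        raise KeyError(f"unknown pipeline stage {stage!r}")
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))
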