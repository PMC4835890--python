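"""Deterministic per-stage seed derivation.

Each pipeline stage (and each replicate cohort in calibration
experiments) gets its own generator derived from the master seed and a
stage name, via a stable hash of the name. Adding or reordering stages
therefore never reshuffles the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(master_seed: int, stage: str) -> int:
    """A stable 31-bit seed for one named stage."""
    ss = np.random.SeedSequence([int(master_seed) % _MOD, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % _MOD)


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))
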