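"""Deterministic seed derivation.

Every stage draws its randomness from a child of the master seed obtained via
``stage_seed(master, stage, *indices)``; the stage name is hashed with CRC-32
so partial re-runs of any stage reproduce the full run's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(master: int, stage: str, *indices: int) -> np.random.SeedSequence:
    """SeedSequence for a named stage (optionally indexed, e.g. round/client)."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, tag, *[int(i) for i in indices]])


def stage_rng(master: int, stage: str, *indices: int) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master, stage, *indices))
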