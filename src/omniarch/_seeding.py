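"""Deterministic per-stage random streams.

Every source of randomness in the package derives from a single master seed
via :func:`stage_rng`, so that independent pipeline stages draw from
non-overlapping streams while the whole run stays reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit integer seed for a named stage."""
    crc = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) % (2**31), spawn_key=(crc,))
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return a Generator whose stream depends on (master_seed, stage) only."""
    crc = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) % (2**31), spawn_key=(crc,))
    return np.random.default_rng(ss)
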