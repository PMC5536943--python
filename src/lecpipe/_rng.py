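"""Deterministic per-stage random streams.

One top-level seed feeds a named substream per pipeline stage, so each stage
is reproducible on its own and insensitive to whether earlier stages ran.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, name: str) -> int:
    """A stable 31-bit seed for stage ``name`` derived from the master seed."""
    return (int(seed) ^ zlib.crc32(name.encode())) & 0x7FFFFFFF


def stage_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))
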