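"""Deterministic random-stream derivation.

Every stochastic operation in the package takes one integer seed and derives
named sub-streams from it, so draws for one entity never depend on how many
other entities exist or on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def substream(seed: int, *tags) -> np.random.Generator:
    """A generator keyed by ``seed`` plus a fixed sequence of string/int tags."""
    entropy = [int(seed) & 0xFFFFFFFFFFFFFFFF] + [_key(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
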