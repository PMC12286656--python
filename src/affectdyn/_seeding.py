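"""Deterministic per-stream random substreams.

A single integer session seed is split into named substreams so that every
generator (event timing, unit noise, LFP background, ...) is independently
reproducible: stream = SeedSequence([seed, crc32(name)]).  Identical
(seed, name) pairs always yield bit-identical draws regardless of the order
in which streams are consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), key])))
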