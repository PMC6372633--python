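"""Deterministic named RNG substreams.

One global integer seed fans out into independent, order-insensitive
substreams, one per stochastic operation, so partial reruns of a pipeline
reuse exactly the same randomness per stage.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across platforms and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def spawn_seed(seed: int, name: str) -> int:
    """Derive a child integer seed for APIs that take seeds, not Generators."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])
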