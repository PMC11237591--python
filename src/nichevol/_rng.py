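"""Seed management: one master seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the stage name, so every stage draws
    from an independent, reproducible stream of the one master seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def child_seed(seed: int, name: str) -> int:
    """Derive a small integer seed (< 2**31) for the named substream."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
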