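"""Seed discipline: named substreams derived from one global seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a reproducible generator for (seed, name).

    All package randomness flows through this function so that a single
    global seed determines every artifact, while distinct module stream
    names stay statistically independent.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed) & 0xFFFFFFFF, tag)))
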