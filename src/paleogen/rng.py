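"""Seeded random-stream plumbing.

Every stochastic operation takes an explicit seed (or Generator) and draws
from its own labeled substream, so adding a pipeline stage never perturbs
the draws of another stage.  Substreams are derived from (seed, label) via
CRC32 of the label, which is stable across platforms and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


def as_generator(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
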