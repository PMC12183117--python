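"""Named random substreams derived from one top-level seed.

Every source of randomness in the package (splits, parameter init,
dropout, shuffling, simulation) draws from a substream keyed by a short
name, so one integer seed pins down an entire run while components stay
statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator for the (*seed*, *name*) substream; deterministic."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def substream_seed(seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(seed, f"{name}:{index}").integers(0, 2**31))
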