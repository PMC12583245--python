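"""Named random substreams so every stage draws from an independent,
reproducible stream derived from one root seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tuple of stream names.

    The same (seed, names) always yields the same stream; different names
    yield statistically independent streams.  Insensitive to call order.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for name in names:
        keys.append(zlib.crc32(str(name).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(keys))
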