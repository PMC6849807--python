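"""Small shared helpers: significant-figure rounding and seeded RNG streams."""

from __future__ import annotations

import math
import zlib

import numpy as np


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures; passes through 0, inf and nan."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


def stream(seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic child RNG derived from a root seed and string/int keys.

    String keys are hashed with crc32 so the stream depends only on the key
    text, never on interpreter hash randomisation.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode("utf-8")))
        else:
            words.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
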