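"""Root-seed handling: every source of randomness draws from a named
substream of one root seed, so individual studies (splits, negative
sampling, initialization, masking) are independently reproducible."""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    return int(np.random.SeedSequence(
        [int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]
    ).generate_state(1)[0] & 0x7FFFFFFF)


def named_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(root_seed, name))
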