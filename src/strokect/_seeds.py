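"""Deterministic derivation of per-stage sub-seeds from one global seed."""
from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, name: str) -> int:
    """Stable sub-seed for a named source of randomness (< 2**31)."""
    return int(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
               .generate_state(1)[0] % (2 ** 31))


def subrng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, name))
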