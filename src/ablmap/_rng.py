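"""Named random-number streams.

All randomness in the package flows from one integer seed through
:func:`stream`, which derives an independent ``numpy`` generator from the seed
plus a tuple of string/int keys (e.g. ``("sim", mouse_id, fov_id, "noise")``).
Subsetting a simulation (fewer mice, fewer FOVs) therefore reproduces exactly
the draws of the full run for the entities that remain.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_hash(key: object) -> int:
    return zlib.crc32(repr(key).encode("utf-8")) % (2**31)


def stream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator deterministically derived from ``seed`` and ``keys``."""
    entropy = [int(seed) % (2**31)] + [_key_hash(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *keys: object) -> int:
    """A plain integer seed (< 2**31) derived from ``seed`` and ``keys``."""
    return int(stream(seed, *keys).integers(0, 2**31))
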