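"""Small shared numerical helpers."""

from __future__ import annotations

import zlib

import numpy as np


def round_half_away(x):
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    numpy's default rounding is banker's rounding; averaged rarefaction counts
    are rounded half away from zero because the convention changes
    presence/absence at the margin and must be stated.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Derive a reproducible random substream from a master seed and a label.

    Labels are hashed with CRC32 so that adding or removing one stream never
    perturbs the draws of any other stream.
    """
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return np.random.default_rng(ss)


def as_1d_float(x, name: str):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr
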