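"""Shared helpers: named random substreams and small validation utilities."""

from __future__ import annotations

import hashlib

import numpy as np

from .errors import ParameterError

__all__ = ["substream", "check_fraction", "check_positive"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for a named substream of the master seed.

    Each generator in the package draws from its own substream, keyed by a
    stable hash of ``name``, so adding or reordering generators never
    perturbs the draws of the others.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


def check_fraction(value: float, field: str, *, closed_low: bool = True) -> float:
    value = float(value)
    low_ok = value >= 0 if closed_low else value > 0
    if not (low_ok and value <= 1):
        raise ParameterError(f"{field} must be a fraction in [0, 1], got {value!r}")
    return value


def check_positive(value, field: str, *, integer: bool = False):
    if integer:
        if int(value) != value or value < 1:
            raise ParameterError(f"{field} must be a positive integer, got {value!r}")
        return int(value)
    if not value > 0:
        raise ParameterError(f"{field} must be positive, got {value!r}")
    return float(value)
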