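"""Shared helpers: seeded substreams and error types."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["ConfigError", "DataError", "derive_seed", "substream"]

_MOD = 2**31


class ConfigError(ValueError):
    """Invalid configuration (schema violation, out-of-range parameter)."""


class DataError(ValueError):
    """Invalid or inconsistent input data."""


def derive_seed(seed: int, label: str) -> int:
    """Derive a labeled child seed from a run seed.

    Labeled substreams keep the random draws of one stage (e.g. elongation
    fates) independent of another (fragment sampling), so changing the
    number of fragments requested never perturbs the simulated fates.
    """
    mix = zlib.crc32(label.encode("utf-8"))
    return (int(seed) * 2654435761 + mix) % _MOD


def substream(seed: int, label: str) -> np.random.Generator:
    """A NumPy generator seeded from (seed, label)."""
    return np.random.default_rng(np.random.SeedSequence([derive_seed(seed, label), zlib.crc32(label.encode("utf-8")) % _MOD]))
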