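"""Shared small helpers: seeding, chromosome-label normalisation, errors."""

from __future__ import annotations

import numpy as np

__all__ = [
    "DataError",
    "DegenerateInputError",
    "spawn_rngs",
    "normalize_chrom",
    "chrom_sort_key",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


class DegenerateInputError(DataError):
    """Raised when an input is structurally valid but degenerate (e.g. all-zero matrix)."""


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one seed.

    Uses ``numpy.random.SeedSequence.spawn`` so derived streams are
    statistically independent and stable across runs.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def normalize_chrom(label) -> str:
    """Map 'chr1'/'Chr1'/'1' to a canonical '1'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def chrom_sort_key(label: str):
    """Sort numerically named chromosomes before lexical ones (1..22, then X, Y, MT...)."""
    s = normalize_chrom(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)
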