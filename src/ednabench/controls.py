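"""Negative-control query datasets.

Two kinds of negative control probe classifier false positives: purely
random sequences, and "surrogate" off-target regions cut from unrelated
genes (e.g. bacterial rRNA) to marker-product-like lengths.  A correct
classifier should assign no in-scope species to either.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sequtils import random_dna

__all__ = ["ControlSpec", "MARKER_LENGTH_RANGES", "random_genes", "surrogate_regions"]

#: Default surrogate-region length windows per marker, chosen to match the
#: typical product sizes of the common 12S/16S/COI metabarcoding primers.
MARKER_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "12S": (164, 191),
    "16S": (149, 240),
    "COI": (310, 313),
}


@dataclass(frozen=True)
class ControlSpec:
    kind: str  # 'random' | 'surrogate'
    n: int = 100
    length: int = 170
    length_range: tuple[int, int] = (164, 191)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "surrogate"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length range must satisfy 0 < min <= max")


def random_genes(n: int = 100, length: int = 170, seed: int = 0) -> list[tuple[str, str]]:
    """``n`` i.i.d.-uniform A/C/G/T sequences of exactly ``length`` bases.

    Defaults (100 × 170 bp) produce a random negative-control library of
    roughly 16S-product-sized "genes".  Deterministic given ``seed``.
    """
    if n < 0 or length < 1:
        raise ValueError("n must be >= 0 and length >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    return [(f"random_{i + 1:04d}", random_dna(rng, length)) for i in range(n)]


def surrogate_regions(
    genes: list[tuple[str, str]],
    length_range: tuple[int, int] = (164, 191),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Cut one marker-product-sized window from each source gene.

    The window length is drawn uniformly from ``length_range`` (capped at
    the gene length) and its start uniformly among valid positions.  Genes
    shorter than the minimum are skipped with a warning.  Deterministic
    given ``seed``.
    """
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("length range must satisfy 0 < min <= max")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    out: list[tuple[str, str]] = []
    for gid, seq in genes:
        if len(seq) < lo:
            warnings.warn(f"gene {gid} shorter than {lo} bp; skipped", stacklevel=2)
            continue
        want = int(rng.integers(lo, hi + 1))
        length = min(want, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        out.append((f"{gid}|{start}-{start + length}", seq[start : start + length]))
    return out
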