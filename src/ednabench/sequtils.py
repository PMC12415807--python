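"""Nucleotide helpers shared across modules: IUPAC semantics, complements."""

from __future__ import annotations

import numpy as np

#: IUPAC code → 4-bit set over (A=1, C=2, G=4, T=8).
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)

#: dense lookup from byte value to mask (0 for non-IUPAC characters)
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R↔Y, S↔S, N↔N, ...)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_masks(seq: str) -> np.ndarray:
    """Encode a sequence as an array of 4-bit base sets."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if (masks == 0).any():
        bad = seq[int(np.argmax(masks == 0))]
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return masks


def bases_match(a: str, b: str) -> bool:
    """True when the IUPAC sets of two codes intersect (e.g. R matches A)."""
    return bool(IUPAC_MASK[a.upper()] & IUPAC_MASK[b.upper()])


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. sequence over {A,C,G,T}."""
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at ``rate``; each hit draws one of the
    3 alternative bases uniformly.  Substitution-only (no indels)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)
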