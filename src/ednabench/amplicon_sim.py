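"""In-silico PCR, representative selection, read simulation and ASVs.

The simulation chain mirrors a metabarcoding wet-lab workflow:

1. ``amplify``: degenerate primers scanned against both template strands
   with a per-primer mismatch budget (no indels); products within length
   bounds are emitted primer-trimmed, in forward-primer orientation.
2. ``select_representatives``: a greedy max–min design over k-mer Jaccard
   distances that picks a diverse species panel from a pool of amplicons.
3. ``simulate_reads``: paired-end reads from each amplicon end with i.i.d.
   substitution errors and a flat Phred quality.
4. ``derive_asvs``: exact dereplication into amplicon sequence variants,
   keeping the source-species provenance that later defines ground truth.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .refdb import ReferenceDB
from .sequtils import iupac_masks, revcomp
from .taxonomy import Lineage

__all__ = [
    "Primer",
    "Amplicon",
    "ReadPair",
    "ASV",
    "amplify",
    "amplify_db",
    "select_representatives",
    "simulate_reads",
    "derive_asvs",
]


@dataclass(frozen=True)
class Primer:
    """A PCR primer pair; both sequences written 5'→3' on their own strand."""

    name: str
    forward: str
    reverse: str
    max_mismatches: int = 4
    min_length: int = 1
    max_length: int = 10_000

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("product length bounds must satisfy 0 < min <= max")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    """A primer-trimmed PCR product with provenance back to its template."""

    amplicon_id: str
    source_id: str
    source_lineage: Lineage
    start: int  # 0-based half-open interval on the template, primers included
    end: int
    strand: str  # '+' or '-'
    sequence: str  # inter-primer region, forward-primer orientation

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid template interval")


@dataclass(frozen=True)
class ReadPair:
    read1: str
    read2: str
    qual1: str
    qual2: str
    amplicon_id: str
    pair_index: int

    def __post_init__(self) -> None:
        if len(self.read1) != len(self.qual1) or len(self.read2) != len(self.qual2):
            raise ValueError("quality string length must equal read length")


@dataclass
class ASV:
    """A dereplicated amplicon sequence variant with source provenance."""

    asv_id: str
    sequence: str
    provenance: list[Lineage]  # multiset of source-species lineages
    support: int


# ---------------------------------------------------------------------------
# in-silico PCR


def _primer_sites(template_masks: np.ndarray, primer: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of ungapped primer placements within budget."""
    pm = primer_masks = iupac_masks(primer)
    L, m = len(template_masks), len(primer_masks)
    if L < m:
        return []
    mism = np.zeros(L - m + 1, dtype=np.int32)
    for j in range(m):
        mism += (template_masks[j : L - m + 1 + j] & pm[j]) == 0
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mm)[0]]


def _scan_strand(template: str, primer: Primer) -> list[tuple[int, int, str]]:
    """Forward/reverse site pairings on one strand.

    Returns (start, end, inter-primer sequence) with coordinates on the
    scanned strand; ``start``/``end`` span the full product incl. primers.
    """
    tm = iupac_masks(template)
    fwd_sites = _primer_sites(tm, primer.forward, primer.max_mismatches)
    rev_probe = revcomp(primer.reverse)  # reverse primer as seen on this strand
    rev_sites = _primer_sites(tm, rev_probe, primer.max_mismatches)
    out = []
    flen, rlen = len(primer.forward), len(rev_probe)
    for fs, _ in fwd_sites:
        ins_start = fs + flen
        for rs, _ in rev_sites:
            if rs < ins_start:
                continue
            insert = template[ins_start:rs]
            if primer.min_length <= len(insert) <= primer.max_length:
                out.append((fs, rs + rlen, insert))
    return out


def amplify(
    template: str,
    primer: Primer,
    *,
    source_id: str = "template",
    source_lineage: Lineage = Lineage(()),
    keep_primers: bool = False,
) -> list[Amplicon]:
    """Find every primer-pair product on either strand of ``template``.

    Primer placement is ungapped; a template/primer column matches when the
    two IUPAC base sets intersect (so primer R over template A matches, and
    template N matches anything).  Products are primer-trimmed unless
    ``keep_primers``; duplicates arising from palindromic sites are removed.
    No site simply yields an empty list.
    """
    L = len(template)
    found: dict[tuple[int, int, str], tuple[str, str]] = {}
    for strand in "+-":
        seq = template if strand == "+" else revcomp(template)
        for s, e, insert in _scan_strand(seq, primer):
            if strand == "+":
                interval = (s, e)
            else:  # map back to forward-strand coordinates
                interval = (L - e, L - s)
            product = insert if not keep_primers else seq[s:e]
            key = (interval[0], interval[1], product)
            if key not in found:  # '+' scanned first wins on palindromes
                found[key] = (strand, product)
    amplicons = []
    for i, key in enumerate(sorted(found)):
        start, end, _ = key
        strand, product = found[key]
        amplicons.append(
            Amplicon(
                amplicon_id=f"{source_id}.amp{i}",
                source_id=source_id,
                source_lineage=source_lineage,
                start=start,
                end=end,
                strand=strand,
                sequence=product,
            )
        )
    return amplicons


def amplify_db(db: ReferenceDB, primer: Primer) -> list[Amplicon]:
    """Run ``amplify`` over every record of a reference DB (stable order)."""
    out: list[Amplicon] = []
    for rec in db.records:
        for amp in amplify(
            rec.sequence, primer, source_id=rec.seqid, source_lineage=rec.lineage
        ):
            out.append(amp)
    return out


# ---------------------------------------------------------------------------
# representative selection


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    union = len(a | b)
    return 1.0 - len(a & b) / union


def select_representatives(
    sequences: list[tuple[str, str]], n: int, seed: int = 0, k: int = 8
) -> list[str]:
    """Pick ``n`` mutually distant sequences by greedy max–min design.

    Distances are k-mer Jaccard (k=8 default).  The first pick maximises
    mean distance to all others; each later pick maximises its minimum
    distance to the chosen set.  Exact ties are broken by a seed-derived
    random priority, so the selection is deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    ids = [sid for sid, _ in sequences]
    if n >= len(ids):
        return list(ids)
    sets = [_kmer_set(s, k) for _, s in sequences]
    m = len(ids)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = _jaccard_distance(sets[i], sets[j])
    rng = np.random.default_rng(seed)
    priority = rng.permutation(m)  # tie-break order

    mean_d = D.sum(axis=1) / (m - 1)
    first = max(range(m), key=lambda i: (mean_d[i], priority[i]))
    chosen = [first]
    min_d = D[first].copy()
    while len(chosen) < n:
        cand = max(
            (i for i in range(m) if i not in chosen),
            key=lambda i: (min_d[i], priority[i]),
        )
        chosen.append(cand)
        np.minimum(min_d, D[cand], out=min_d)
    return [ids[i] for i in chosen]


# ---------------------------------------------------------------------------
# read simulation

_MAX_RETRIES = 50


def simulate_reads(
    amplicon: Amplicon,
    n_pairs: int = 500,
    read_length: int = 130,
    substitution_rate: float = 0.0,
    base_quality: int = 35,
    min_quality: int = 0,
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads from one amplicon.

    Read 1 is the 5' prefix of the amplicon and read 2 the reverse
    complement of its 3' suffix, each truncated to ``read_length`` (500
    pairs per gene copy and 130 bp reads by default, the depths and lengths
    typical of amplicon runs).  Substitution errors are i.i.d. per base at
    ``substitution_rate``, drawing uniformly among the 3 alternative bases.
    Qualities are a flat Phred value; pairs whose mean quality falls below
    ``min_quality`` are regenerated, with a bounded retry budget.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    seq = amplicon.sequence
    rl = min(read_length, len(seq))
    fwd = seq[:rl]
    rev = revcomp(seq)[:rl]
    qual = chr(base_quality + 33) * rl
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)

    def mutate_read(read: str) -> str:
        if substitution_rate == 0:
            return read
        arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(rl) < substitution_rate)[0]
        for i in hits:
            alts = base_lut[base_lut != arr[i]]
            arr[i] = alts[rng.integers(len(alts))]
        return arr.tobytes().decode("ascii")

    pairs: list[ReadPair] = []
    for idx in range(n_pairs):
        for attempt in range(_MAX_RETRIES):
            r1, r2 = mutate_read(fwd), mutate_read(rev)
            mean_q = base_quality  # flat quality profile
            if mean_q >= min_quality:
                pairs.append(ReadPair(r1, r2, qual, qual, amplicon.amplicon_id, idx))
                break
        else:
            raise RuntimeError(
                f"min_quality={min_quality} unattainable with base_quality="
                f"{base_quality} after {_MAX_RETRIES} retries"
            )
    return pairs


# ---------------------------------------------------------------------------
# ASV derivation


def merge_pair(pair: ReadPair, min_overlap: int = 10) -> str | None:
    """Merge a read pair by exact suffix/prefix overlap; None if unmergeable."""
    r1 = pair.read1
    rc2 = revcomp(pair.read2)
    limit = min(len(r1), len(rc2))
    for o in range(limit, min_overlap - 1, -1):
        if r1[-o:] == rc2[:o]:
            return r1 + rc2[o:]
    return None


def derive_asvs(
    items: list[Amplicon] | list[ReadPair],
    mode: str = "dereplicate-amplicons",
    min_support: int = 1,
    provenance: dict[str, Lineage] | None = None,
) -> list[ASV]:
    """Collapse identical sequences into ASVs with species provenance.

    ``dereplicate-amplicons`` collapses amplicon sequences directly (one
    count per amplicon).  ``dereplicate-merged-reads`` merges each read pair
    by exact overlap first (unmergeable pairs are dropped with a warning);
    ``provenance`` then maps amplicon ids to source lineages.  ASVs below
    ``min_support`` are removed; ids are assigned in decreasing-support,
    then lexicographic-sequence order.
    """
    if not items:
        raise ValueError("derive_asvs requires a non-empty input")
    seq_counts: dict[str, int] = defaultdict(int)
    seq_prov: dict[str, list[Lineage]] = defaultdict(list)

    if mode == "dereplicate-amplicons":
        for amp in items:
            seq_counts[amp.sequence] += 1
            seq_prov[amp.sequence].append(amp.source_lineage)
    elif mode == "dereplicate-merged-reads":
        prov = provenance or {}
        dropped = 0
        for pair in items:
            merged = merge_pair(pair)
            if merged is None:
                dropped += 1
                continue
            seq_counts[merged] += 1
            lin = prov.get(pair.amplicon_id)
            if lin is not None:
                seq_prov[merged].append(lin)
        if dropped:
            warnings.warn(f"{dropped} read pair(s) had no exact overlap; dropped", stacklevel=2)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ordered = sorted(seq_counts, key=lambda s: (-seq_counts[s], s))
    asvs = []
    width = max(4, len(str(len(ordered))))
    for i, seq in enumerate(ordered):
        if seq_counts[seq] < min_support:
            continue
        asvs.append(
            ASV(
                asv_id=f"ASV_{i + 1:0{width}d}",
                sequence=seq,
                provenance=list(seq_prov[seq]),
                support=seq_counts[seq],
            )
        )
    return asvs
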