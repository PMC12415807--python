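"""Marker reference databases: curation and clade-exclusion variants.

A ReferenceDB joins nucleotide records for one marker (12S/16S/COI) to
ranked lineages.  Two curation-style operations are provided:

* ``detect_mislabels`` — an all-vs-all self-search that flags records whose
  high-identity neighbours sit in a different family, using an LCA test and
  a family majority vote (the minority family in a conflict set is the
  suspected mislabel).
* ``exclude_families`` — builds "clade exclusion" database variants by
  removing whole families at random, emulating incomplete reference
  databases so false-positive behaviour can be measured.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import align_semiglobal
from .taxonomy import Lineage, lca

__all__ = [
    "RefRecord",
    "ReferenceDB",
    "ExclusionPlan",
    "MislabelFlag",
    "detect_mislabels",
    "exclude_families",
    "load_refdb",
]


@dataclass(frozen=True)
class RefRecord:
    seqid: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.seqid!r} has an empty sequence")
        if self.lineage.family is None:
            raise ValueError(f"record {self.seqid!r} lineage has no family")


@dataclass
class ReferenceDB:
    """Marker-tagged reference records with a derived family index."""

    marker: str
    records: list[RefRecord]

    def __post_init__(self) -> None:
        ids = [r.seqid for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in ReferenceDB: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def families(self) -> dict[str, list[RefRecord]]:
        idx: dict[str, list[RefRecord]] = {}
        for rec in self.records:
            idx.setdefault(rec.lineage.family, []).append(rec)
        return idx

    @property
    def species(self) -> set[str]:
        return {r.lineage.species for r in self.records if r.lineage.species}

    def get(self, seqid: str) -> RefRecord:
        for rec in self.records:
            if rec.seqid == seqid:
                return rec
        raise KeyError(seqid)

    def drop(self, seqids: set[str]) -> "ReferenceDB":
        """New DB without the given records (records kept byte-identical)."""
        return ReferenceDB(self.marker, [r for r in self.records if r.seqid not in seqids])


@dataclass(frozen=True)
class ExclusionPlan:
    """Which families a clade-exclusion variant removes, and why."""

    fraction: float
    seed: int
    replicate: int
    excluded: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "fraction": self.fraction,
                "seed": self.seed,
                "replicate": self.replicate,
                "excluded": list(self.excluded),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExclusionPlan":
        d = json.loads(text)
        return cls(d["fraction"], d["seed"], d["replicate"], tuple(d["excluded"]))


@dataclass(frozen=True)
class MislabelFlag:
    seqid: str
    reason: str
    minority_family: str = ""
    conflict_set: tuple[str, ...] = field(default=(), compare=False)


def load_refdb(fasta_path, lineage_path, marker: str = "12S") -> ReferenceDB:
    """Load a reference DB from FASTA (headers = sequence ids) + lineage TSV."""
    from Bio import SeqIO

    from .taxonomy import read_lineage_tsv

    table = read_lineage_tsv(lineage_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in table.lineages:
            raise KeyError(f"sequence {rec.id!r} has no lineage row")
        records.append(RefRecord(rec.id, str(rec.seq).upper(), table.lineages[rec.id]))
    return ReferenceDB(marker, records)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def n_families_to_exclude(n_families: int, fraction: float) -> int:
    """Nearest-integer count (half away from zero), floor 1 when fraction>0."""
    if fraction == 0:
        return 0
    return min(n_families, max(1, _round_half_away(fraction * n_families)))


def exclude_families(
    db: ReferenceDB, fraction: float, seed: int, replicate: int = 0
) -> tuple[ReferenceDB, ExclusionPlan]:
    """Remove a random ``fraction`` of whole families from ``db``.

    The family draw is a pure function of (db families, fraction, seed,
    replicate): each (seed, replicate) pair names its own pseudorandom
    stream, so replicates are independent but individually reproducible.
    Retained records are the parent's objects, byte-identical.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be within [0, 1], got {fraction}")
    fams = sorted(db.families)
    k = n_families_to_exclude(len(fams), fraction)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))
    excluded = tuple(sorted(str(f) for f in rng.choice(fams, size=k, replace=False))) if k else ()
    plan = ExclusionPlan(fraction, seed, replicate, excluded)
    gone = set(excluded)
    kept = [r for r in db.records if r.lineage.family not in gone]
    return ReferenceDB(db.marker, kept), plan


def detect_mislabels(
    db: ReferenceDB,
    min_identity: float = 0.97,
    min_query_coverage: float = 1.0,
) -> list[MislabelFlag]:
    """Flag records whose near-identical neighbours belong to another family.

    For every query record, all other records are overlap-aligned; subjects
    with identity strictly above ``min_identity`` and query coverage at least
    ``min_query_coverage`` are retained.  If the LCA of the query plus its
    retained subjects is shallower than family, the families in that conflict
    set are tallied and every sequence of the minority family is flagged.
    Ties between family counts flag nothing and emit a warning (removing data
    on a tie risks deleting correct records).  Flags are deduplicated and
    sorted by sequence id.
    """
    if not db.records:
        raise ValueError("detect_mislabels requires a non-empty ReferenceDB")
    if len(db.records) < 2:
        raise ValueError("detect_mislabels requires at least 2 records")

    flags: dict[str, MislabelFlag] = {}
    for query in db.records:
        subjects = []
        for subj in db.records:
            if subj.seqid == query.seqid:
                continue
            res = align_semiglobal(query.sequence, subj.sequence, subj.seqid)
            if res.identity > min_identity and res.coverage >= min_query_coverage:
                subjects.append(subj)
        if not subjects:
            continue
        group = [query] + subjects
        anc = lca([r.lineage for r in group])
        if anc.family is not None:
            continue  # all one family: consistent labels
        counts: dict[str, int] = {}
        for rec in group:
            counts[rec.lineage.family] = counts.get(rec.lineage.family, 0) + 1
        least = min(counts.values())
        minority = [f for f, c in counts.items() if c == least]
        if len(minority) > 1 or len(counts) == len(minority):
            warnings.warn(
                f"mislabel vote tie among families {sorted(counts)} "
                f"(query {query.seqid}); nothing flagged",
                stacklevel=2,
            )
            continue
        bad_family = minority[0]
        members = tuple(sorted(r.seqid for r in group))
        for rec in group:
            if rec.lineage.family == bad_family and rec.seqid not in flags:
                flags[rec.seqid] = MislabelFlag(
                    seqid=rec.seqid,
                    reason=(
                        f"family {bad_family} is the minority "
                        f"({counts[bad_family]} of {len(group)}) in a >"
                        f"{min_identity:.0%}-identity conflict set"
                    ),
                    minority_family=bad_family,
                    conflict_set=members,
                )
    return [flags[k] for k in sorted(flags)]
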