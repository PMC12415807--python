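"""Ranked lineages and lowest-common-ancestor queries.

The toolkit works on a fixed, canonical rank ladder — class, order, family,
genus, species — because marker-gene benchmarks are scored at species, genus
and family level and reference databases are curated per family.  Ranks
outside this ladder (phylum, subfamily, ...) present in input lineage strings
are ignored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: Canonical ranks, shallowest first.
RANKS: tuple[str, ...] = ("class", "order", "family", "genus", "species")

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Base class for lineage/taxonomy construction errors."""


class MissingFamilyError(TaxonomyError):
    """A lineage row does not define a family."""


class DuplicateSequenceIdError(TaxonomyError):
    """The same sequence id appears in more than one row."""


@dataclass(frozen=True)
class Lineage:
    """An ordered rank→name mapping over the canonical ranks.

    A lineage may be truncated: entries exist for some prefix of the rank
    ladder (e.g. class..genus for a genus-level assignment).  Numeric taxon
    ids, when known, ride along as annotations and play no role in identity.
    """

    names: tuple[str, ...]  # aligned with RANKS, truncated at the deepest rank
    taxids: tuple[int | None, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise TaxonomyError(f"lineage has {len(self.names)} ranks; max {len(RANKS)}")
        if any(not n for n in self.names):
            raise TaxonomyError("lineage contains an empty rank name (not truncated)")

    # -- accessors --------------------------------------------------------

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0 = completely unassigned)."""
        return len(self.names)

    @property
    def deepest_rank(self) -> str | None:
        return RANKS[len(self.names) - 1] if self.names else None

    def name_at(self, rank: str) -> str | None:
        i = _RANK_DEPTH[rank]
        return self.names[i] if i < len(self.names) else None

    @property
    def species(self) -> str | None:
        return self.name_at("species")

    @property
    def genus(self) -> str | None:
        return self.name_at("genus")

    @property
    def family(self) -> str | None:
        return self.name_at("family")

    def truncate(self, rank: str | None) -> "Lineage":
        """Return this lineage cut at ``rank`` (None → empty lineage)."""
        if rank is None:
            return Lineage(())
        i = _RANK_DEPTH[rank] + 1
        return Lineage(self.names[:i], self.taxids[:i])

    def items(self) -> Iterable[tuple[str, str]]:
        return zip(RANKS, self.names)

    def __str__(self) -> str:
        return ";".join(self.names)

    @classmethod
    def from_names(cls, **by_rank: str | None) -> "Lineage":
        """Build from keyword rank names; must form a contiguous prefix."""
        names = []
        for r in RANKS:
            v = by_rank.get(r)
            if v is None:
                break
            names.append(v)
        extra = [r for r in RANKS if by_rank.get(r) and r not in dict(zip(RANKS, names))]
        if extra:
            raise TaxonomyError(f"non-contiguous lineage: rank(s) {extra} assigned below a gap")
        return cls(tuple(names))


EMPTY_LINEAGE = Lineage(())


def parse_lineage_string(text: str, *, deepest_first: bool = False, sep: str = ";") -> Lineage:
    """Parse a delimited lineage string into a canonical :class:`Lineage`.

    With ``deepest_first=False`` (the default dialect) the string lists ranks
    shallowest-first / deepest-last, e.g.::

        Chordata;Actinopteri;Perciformes;Lutjanidae;Lutjanus;Lutjanus jocu

    When more than five fields are present the *deep* end anchors the
    assignment, so ranks above class (phylum, kingdom, ...) are dropped.
    Fewer than five fields assign from class downward (a truncated lineage).
    """
    fields = [f.strip() for f in text.split(sep)]
    fields = [f for f in fields if f != ""]
    if deepest_first:
        fields = fields[::-1]
    if len(fields) >= len(RANKS):
        names = fields[-len(RANKS):]
    else:
        names = fields  # truncated lineage: class downward
    return Lineage(tuple(names))


@dataclass
class TaxonomyTable:
    """Sequence-id → lineage mapping plus a family index."""

    lineages: dict[str, Lineage]
    families: dict[str, set[str]]

    def __len__(self) -> int:
        return len(self.lineages)

    def __getitem__(self, seqid: str) -> Lineage:
        return self.lineages[seqid]

    def name_to_lineage(self) -> dict[str, Lineage]:
        """Map every known taxon name at any rank to a lineage truncated there.

        Names claimed at more than one position keep the deepest occurrence.
        """
        out: dict[str, Lineage] = {}
        for lin in self.lineages.values():
            for rank, name in lin.items():
                cut = lin.truncate(rank)
                prev = out.get(name)
                if prev is None or cut.depth > prev.depth:
                    out[name] = cut
        return out


def build_taxonomy(
    rows: Iterable[tuple[str, str]], *, deepest_first: bool = False
) -> TaxonomyTable:
    """Build a :class:`TaxonomyTable` from (sequence-id, lineage-string) rows.

    Rows lacking a family rank are rejected with :class:`MissingFamilyError`;
    duplicate sequence ids raise :class:`DuplicateSequenceIdError`.
    """
    lineages: dict[str, Lineage] = {}
    families: dict[str, set[str]] = defaultdict(set)
    for seqid, text in rows:
        if seqid in lineages:
            raise DuplicateSequenceIdError(f"duplicate sequence id {seqid!r}")
        lin = parse_lineage_string(text, deepest_first=deepest_first)
        if lin.family is None:
            raise MissingFamilyError(f"row {seqid!r}: lineage {text!r} has no family rank")
        lineages[seqid] = lin
        families[lin.family].add(seqid)
    return TaxonomyTable(lineages, dict(families))


def read_lineage_tsv(path, *, deepest_first: bool = False) -> TaxonomyTable:
    """Read the lineage TSV dialect: ``seqid<TAB>class;order;...;species``.

    UTF-8; lines starting with '#' are comments.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seqid, _, lineage = line.partition("\t")
            rows.append((seqid, lineage))
    return build_taxonomy(rows, deepest_first=deepest_first)


def write_lineage_tsv(path, lineages: Mapping[str, Lineage]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seqid in lineages:
            fh.write(f"{seqid}\t{lineages[seqid]}\n")


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor of a non-empty set of lineages.

    Agreement is by name, rank by rank from class downward; the result is the
    input prefix up to (and including) the deepest rank at which every input
    carries the same name.  Disagreement at class yields the empty lineage.
    """
    if not lineages:
        raise TaxonomyError("lca of an empty lineage list is undefined")
    first = lineages[0]
    depth = 0
    for i in range(len(RANKS)):
        if i >= first.depth:
            break
        name = first.names[i]
        if all(i < l.depth and l.names[i] == name for l in lineages[1:]):
            depth = i + 1
        else:
            break
    return Lineage(first.names[:depth], first.taxids[:depth])
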