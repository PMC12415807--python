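"""Ground-truth labels for simulated ASVs.

Because every simulated amplicon carries its source species, an ASV's truth
is a pure function of its provenance: a single source species gives a
species-level truth; when amplicons from several species collapsed into one
identical sequence, no species label is assignable and the truth falls back
to the LCA of the sources with the species-ambiguity flag set.  Truth never
depends on the classifier's reference database, which is what makes
clade-exclusion experiments scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .amplicon_sim import ASV
from .taxonomy import Lineage, lca

__all__ = ["TruthLabel", "assign_truth", "truth_table", "write_truth_tsv"]


@dataclass(frozen=True)
class TruthLabel:
    """Deepest unambiguous rank for an ASV, plus the lineage cut there."""

    rank: str | None  # 'species'..'class', or None when even class conflicts
    lineage: Lineage
    species_ambiguous: bool
    source_species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        # ambiguity at species <=> the label stops shallower than species
        assert self.species_ambiguous == (self.rank != "species")

    @property
    def species(self) -> str | None:
        return self.lineage.species


def assign_truth(asv: ASV) -> TruthLabel:
    """Derive the ground-truth label from an ASV's provenance multiset."""
    if not asv.provenance:
        raise ValueError(f"ASV {asv.asv_id} has empty provenance")
    species = {lin.species for lin in asv.provenance}
    sources = frozenset(s for s in species if s)
    if len(species) == 1 and None not in species:
        lin = asv.provenance[0].truncate("species")
        return TruthLabel("species", lin, species_ambiguous=False, source_species=sources)
    anc = lca(list(asv.provenance))
    return TruthLabel(anc.deepest_rank, anc, species_ambiguous=True, source_species=sources)


def truth_table(
    asvs: Iterable[ASV], near_identity: float | None = None
) -> dict[str, TruthLabel]:
    """Truth labels for a set of ASVs.

    By default ambiguity is decided by exact-sequence collision only (the
    dereplication boundary).  With ``near_identity`` set (e.g. 0.99), ASVs
    whose sequences align at or above that identity pool their provenance
    first, so nearly identical variants of different species also become
    species-ambiguous.  Exact collision is the default because it is the
    only threshold-free boundary.
    """
    asvs = list(asvs)
    if near_identity is None:
        return {asv.asv_id: assign_truth(asv) for asv in asvs}
    from .align import align_semiglobal

    pooled: dict[str, list[Lineage]] = {a.asv_id: list(a.provenance) for a in asvs}
    for i, a in enumerate(asvs):
        for b in asvs[i + 1 :]:
            res = align_semiglobal(a.sequence, b.sequence)
            if res.identity >= near_identity:
                pooled[a.asv_id].extend(b.provenance)
                pooled[b.asv_id].extend(a.provenance)
    out = {}
    for a in asvs:
        widened = ASV(a.asv_id, a.sequence, pooled[a.asv_id], a.support)
        out[a.asv_id] = assign_truth(widened)
    return out


def write_truth_tsv(path, truths: dict[str, TruthLabel]) -> None:
    """Truth TSV: ``asv_id<TAB>truth_rank<TAB>lineage<TAB>ambiguous``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\ttruth_rank\tlineage\tambiguous\n")
        for asv_id in sorted(truths):
            t = truths[asv_id]
            fh.write(
                f"{asv_id}\t{t.rank or 'none'}\t{t.lineage}\t"
                f"{str(t.species_ambiguous).lower()}\n"
            )
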