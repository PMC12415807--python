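"""Deterministic toy reference databases with planted structure.

Sequences are generated top-down along a rank hierarchy: each family gets a
random ancestral amplicon core, genera mutate that ancestor, species mutate
their genus, and per-species copies optionally mutate again.  Every
sequence embeds exact primer sites flanking the variable core, so in-silico
PCR recovers one amplicon per record with exactly known coordinates
(mutations are substitution-only for the same reason).

Two kinds of defects can be planted, and the manifest records both:

* **mislabels** — an exact copy of a donor-family sequence filed under a
  species of another family, the situation reference-database curation
  should catch;
* **ambiguous pairs** — two congeneric species given literally identical
  amplicons, so their reads collapse into one ASV with no assignable
  species-level truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .amplicon_sim import Primer
from .refdb import RefRecord, ReferenceDB
from .sequtils import mutate, random_dna, revcomp
from .taxonomy import Lineage

__all__ = [
    "FixtureSpec",
    "TOY_PRIMER",
    "PRESETS",
    "make_toy_refdb",
    "bacteria_like_genes",
    "write_refdb",
]

#: Default embedded primer pair (a 12S-style fish marker pair; both written
#: 5'→3' on their own strand, no degenerate bases so fixture matching is exact).
TOY_PRIMER = Primer(
    name="12S_toy",
    forward="GTCGGTAAAACTCGTGCCAGC",
    reverse="CATAGTGGGGTATCTAATCCCAGTTTG",
    max_mismatches=4,
    min_length=50,
    max_length=400,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and divergence parameters of a toy reference database."""

    n_families: int = 4
    genera_per_family: int = 2
    species_per_genus: int = 2
    seqs_per_species: int = 1
    core_length: int = 150
    flank_length: int = 20
    genus_divergence: float = 0.10
    species_divergence: float = 0.02
    within_divergence: float = 0.0
    family_divergence: float | None = None  # None: independent family ancestors
    n_mislabels: int = 0
    n_ambiguous_pairs: int = 0
    primer: Primer = field(default=TOY_PRIMER)
    marker: str = "12S"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_families,
            self.genera_per_family,
            self.species_per_genus,
            self.seqs_per_species,
            self.n_mislabels,
            self.n_ambiguous_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("fixture counts must be >= 0")
        rates = [self.genus_divergence, self.species_divergence, self.within_divergence]
        if self.family_divergence is not None:
            rates.append(self.family_divergence)
        for rate in rates:
            if not 0 <= rate <= 0.75:
                raise ValueError("divergence rates must lie in [0, 0.75]")
        if self.n_ambiguous_pairs and self.species_per_genus < 2:
            raise ValueError("ambiguous pairs need >= 2 species per genus")
        if self.n_mislabels and (self.n_families < 2 or self.species_per_genus < 2):
            raise ValueError("mislabels need >= 2 families and >= 2 species per genus")


def _species_name(fi: int, gi: int, si: int) -> str:
    return f"Fam{fi + 1:02d}g{gi + 1} sp{si + 1}"


def _lineage(fi: int, gi: int, si: int | None = None) -> Lineage:
    names = [
        "Toyclassia",
        f"Order{fi // 2 + 1:02d}",
        f"Fam{fi + 1:02d}",
        f"Fam{fi + 1:02d}g{gi + 1}",
    ]
    if si is not None:
        names.append(_species_name(fi, gi, si))
    return Lineage(tuple(names))


def make_toy_refdb(spec: FixtureSpec) -> tuple[ReferenceDB, dict]:
    """Generate a reference DB plus a manifest of everything planted.

    Fully deterministic given ``spec.seed``: identical specs produce
    byte-identical records.  The manifest lists the planted mislabel ids,
    the planted ambiguous species pairs, and the realized taxonomy.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    fwd_site = spec.primer.forward
    rev_site = revcomp(spec.primer.reverse)

    records: list[RefRecord] = []
    cores: dict[str, str] = {}  # species name -> core of its first copy

    # reserve genera from the *end* for ambiguous pairs so they never share
    # a genus with mislabel donors (reserved from the start)
    all_genera = [
        (fi, gi)
        for fi in range(spec.n_families)
        for gi in range(spec.genera_per_family)
    ]
    if spec.n_ambiguous_pairs > len(all_genera):
        raise ValueError("more ambiguous pairs requested than genera available")
    ambiguous_genera = set(all_genera[len(all_genera) - spec.n_ambiguous_pairs :])

    # with family_divergence set, families descend from one shared root (a
    # "hard" community of close relatives); otherwise families are
    # independent random ancestors (well-separated clades)
    if spec.family_divergence is not None:
        root_core = random_dna(rng, spec.core_length)
        root_flank5 = random_dna(rng, spec.flank_length)
        root_flank3 = random_dna(rng, spec.flank_length)

    for fi in range(spec.n_families):
        if spec.family_divergence is None:
            flank5 = random_dna(rng, spec.flank_length)
            flank3 = random_dna(rng, spec.flank_length)
            family_core = random_dna(rng, spec.core_length)
        else:
            flank5 = mutate(rng, root_flank5, spec.family_divergence)
            flank3 = mutate(rng, root_flank3, spec.family_divergence)
            family_core = mutate(rng, root_core, spec.family_divergence)
        for gi in range(spec.genera_per_family):
            genus_core = mutate(rng, family_core, spec.genus_divergence)
            for si in range(spec.species_per_genus):
                if (fi, gi) in ambiguous_genera and si == 1:
                    species_core = cores[_species_name(fi, gi, 0)]  # planted collision
                else:
                    species_core = mutate(rng, genus_core, spec.species_divergence)
                cores[_species_name(fi, gi, si)] = species_core
                for ci in range(spec.seqs_per_species):
                    core = (
                        species_core
                        if ci == 0
                        else mutate(rng, species_core, spec.within_divergence)
                    )
                    seq = flank5 + fwd_site + core + rev_site + flank3
                    records.append(
                        RefRecord(
                            seqid=f"Fam{fi + 1:02d}g{gi + 1}_sp{si + 1}_c{ci + 1}",
                            sequence=seq,
                            lineage=_lineage(fi, gi, si),
                        )
                    )

    # planted cross-family mislabels: donor species i of genus i, target the
    # next family over; each mislabel uses a fresh donor genus
    mislabel_ids: list[str] = []
    donor_genera = [g for g in all_genera if g not in ambiguous_genera]
    if spec.n_mislabels > len(donor_genera):
        raise ValueError("more mislabels requested than donor genera available")
    by_id = {r.seqid: r for r in records}
    for m in range(spec.n_mislabels):
        fi, gi = donor_genera[m]
        donor = by_id[f"Fam{fi + 1:02d}g{gi + 1}_sp1_c1"]
        target_fi = (fi + 1) % spec.n_families
        bad_id = f"mislabel{m + 1:02d}"
        bad_species = f"Fam{target_fi + 1:02d}g1 spX{m + 1}"
        records.append(
            RefRecord(
                seqid=bad_id,
                sequence=donor.sequence,
                lineage=Lineage(_lineage(target_fi, 0).names + (bad_species,)),
            )
        )
        mislabel_ids.append(bad_id)

    db = ReferenceDB(spec.marker, records)
    manifest = {
        "seed": spec.seed,
        "marker": spec.marker,
        "n_records": len(records),
        "families": sorted(db.families),
        "mislabels": mislabel_ids,
        "ambiguous_pairs": [
            [_species_name(fi, gi, 0), _species_name(fi, gi, 1)]
            for (fi, gi) in sorted(ambiguous_genera)
        ],
        "primer": {
            "name": spec.primer.name,
            "forward": spec.primer.forward,
            "reverse": spec.primer.reverse,
        },
    }
    return db, manifest


def bacteria_like_genes(n: int = 100, length: int = 1200, seed: int = 0) -> list[tuple[str, str]]:
    """Random genes with a GC-rich, bacteria-like base composition.

    These serve as user-supplied source material for the surrogate
    negative control: compositionally distinct from the AT-balanced toy
    marker sequences, and never containing the embedded primer sites.
    """
    if n < 0 or length < 1:
        raise ValueError("n must be >= 0 and length >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    bases = np.array(list("ACGT"))
    probs = np.array([0.18, 0.32, 0.32, 0.18])
    return [
        (f"bact_{i + 1:04d}", "".join(rng.choice(bases, size=length, p=probs)))
        for i in range(n)
    ]


#: Community archetypes: a diverse many-family panel, a single-family set of
#: close congeners, and a mixed panel with intra-species variants.
PRESETS: dict[str, FixtureSpec] = {
    "balanced": FixtureSpec(
        n_families=6, genera_per_family=2, species_per_genus=2,
        genus_divergence=0.12, species_divergence=0.05, seed=0,
    ),
    "similar": FixtureSpec(
        n_families=1, genera_per_family=2, species_per_genus=4,
        species_divergence=0.015, n_ambiguous_pairs=1, seed=0,
    ),
    "realistic-like": FixtureSpec(
        n_families=4, genera_per_family=2, species_per_genus=2,
        seqs_per_species=2, within_divergence=0.005,
        n_ambiguous_pairs=1, seed=0,
    ),
}


def preset(name: str, seed: int = 0) -> FixtureSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def write_refdb(db: ReferenceDB, fasta_path, lineage_path, manifest: dict | None = None,
                manifest_path=None) -> None:
    """Write the FASTA + lineage-TSV dialects (and optionally the manifest)."""
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for rec in db.records:
            fh.write(f">{rec.seqid}\n{rec.sequence}\n")
    with open(lineage_path, "w", encoding="utf-8") as fh:
        for rec in db.records:
            fh.write(f"{rec.seqid}\t{rec.lineage}\n")
    if manifest is not None and manifest_path is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
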