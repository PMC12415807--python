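"""Negative controls: no in-scope species should ever be assigned.

Random sequences and off-target surrogate regions (bacteria-like genes cut
to marker-product length) are classified against a complete reference; any
species assignment would be a false positive.
"""

from ednabench import (
    ASV,
    MARKER_LENGTH_RANGES,
    bacteria_like_genes,
    classify_nbc,
    random_genes,
    surrogate_regions,
    tophit_lca_classify,
    train_nbc,
)
from ednabench.fixtures import FixtureSpec, make_toy_refdb

db, _ = make_toy_refdb(FixtureSpec(
    n_families=6, genera_per_family=2, species_per_genus=2,
    genus_divergence=0.12, species_divergence=0.05, seed=7))
model = train_nbc(db)

randoms = [ASV(gid, seq, [], 1) for gid, seq in random_genes(n=100, length=170, seed=1)]
pool = bacteria_like_genes(n=100, length=600, seed=2)
surrogates = [ASV(gid, seq, [], 1)
              for gid, seq in surrogate_regions(pool, MARKER_LENGTH_RANGES["12S"], seed=3)]

for label, queries in [("random (100 x 170 bp)", randoms),
                       ("surrogate (12S-sized windows)", surrogates)]:
    aln = sum(tophit_lca_classify(q, db, min_identity=0.97).species is not None
              for q in queries)
    nbc = sum(classify_nbc(model, q, prob_cutoff=0.97).species is not None
              for q in queries)
    print(f"{label}: species assignments -> tophit97: {aln}, nbc: {nbc} "
          f"(of {len(queries)} queries)")
# Zero everywhere: at the 97% identity and 0.97 class-probability cutoffs
# neither classifier invents species for out-of-scope sequences.
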