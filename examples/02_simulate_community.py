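"""Simulate an amplicon sequencing experiment with known ground truth.

In-silico PCR extracts the marker region from every reference, paired-end
reads are simulated with substitution errors, merged back, and dereplicated
into ASVs whose provenance (which species produced them) is retained — that
provenance is what defines the truth each classifier is scored against.
"""

from ednabench import (
    TOY_PRIMER,
    amplify_db,
    derive_asvs,
    simulate_reads,
    truth_table,
)
from ednabench.fixtures import FixtureSpec, make_toy_refdb

# one planted pair of congeners with literally identical amplicons
spec = FixtureSpec(n_families=4, n_ambiguous_pairs=1, seed=7)
db, manifest = make_toy_refdb(spec)
amplicons = amplify_db(db, TOY_PRIMER)
print(f"{len(db)} references -> {len(amplicons)} amplicons "
      f"({len(amplicons[0].sequence)} bp inter-primer region)")

pairs, provenance = [], {}
for i, amp in enumerate(amplicons):
    pairs.extend(simulate_reads(amp, n_pairs=50, read_length=130,
                                substitution_rate=0.0, seed=100 + i))
    provenance[amp.amplicon_id] = amp.source_lineage
print(f"simulated {len(pairs)} read pairs (50 per gene copy, 130 bp)")

asvs = derive_asvs(pairs, mode="dereplicate-merged-reads", provenance=provenance)
truths = truth_table(asvs)
ambiguous = [t for t in truths.values() if t.species_ambiguous]
print(f"{len(asvs)} ASVs; {len(ambiguous)} species-ambiguous "
      f"(identical amplicons from different species)")
for t in ambiguous:
    print(f"  ambiguous ASV: truth rank = {t.rank}, "
          f"colliding species = {sorted(t.source_species)}")
print(f"planted collision: {manifest['ambiguous_pairs']}")
# An ambiguous ASV has no true species label: a classifier that names a
# species there is scored as a false positive, abstaining as a true negative.
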