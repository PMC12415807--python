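# Methods

This note documents the models and procedures behind `ednabench`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate
about real eDNA data.

## Scope and data model

The toolkit scores taxonomic classifiers at the species level on simulated
marker-gene (12S/16S/COI) communities. Taxonomy is restricted to a fixed
five-rank ladder — class, order, family, genus, species — because
evaluation happens at species/genus/family and reference curation and
clade exclusion operate on families; ranks outside the ladder in input
lineage strings are ignored, with the deep end of the string anchoring the
assignment. Matching is by name; numeric taxon ids are carried as
annotations only, since synthetic fixtures have no registry ids. The LCA of
a lineage set is the longest rank-wise common prefix by name.

## Overlap alignment

All identity filtering uses one aligner: end-gap-free (overlap) alignment
with unit scores (match +1, mismatch −1, gap −1), free leading/trailing
gaps on both sequences. IUPAC codes match when their base sets intersect.
Reported quantities are **identity** = matches / aligned columns with gap
columns counting as mismatches, and **query coverage** = aligned query
bases / query length. Tie-breaks are fixed (diagonal, then vertical, then
horizontal; alignment ends prefer consuming more of the query), so results
are deterministic. The recurrence is exact for linear gap costs; the
vectorized implementation folds horizontal gap chains with a prefix-max,
and the test suite checks it cell-for-cell against a naive quadratic DP.

Existing alignment libraries were deliberately not used here: none of the
pre-packaged modes (global, prefix-free, infix) implement this exact
both-ends-free scheme together with the identity/coverage definitions
above, and those definitions are what the 97%/100% cutoffs refer to.

## Reference curation (mislabel detection)

Each record is aligned against all others; subjects with identity
strictly above 0.97 and full query coverage are retained (strict ">"
mirrors the curation convention "above 97%", whereas classification uses
"≥"; both are configurable). If the LCA of query + subjects is shallower
than family, the conflict set's family labels are tallied and all members
of the minority family are flagged. Ties flag nothing and warn — deleting
records on a tied vote risks destroying correct data. Flags are restricted
to the sequences participating in the conflict set (the least destructive
reading); callers decide whether to drop them DB-wide.

## Clade exclusion

`exclude_families` removes `round_half_away(fraction × n_families)` whole
families (floor 1 when the fraction is positive; the rounding rule is a
package choice since only percentages are conventionally stated). Each
(seed, replicate) pair names its own pseudorandom stream via
`SeedSequence([seed, replicate])`, never the global generator, so plans
are independently reproducible and a replicate can be regenerated without
replaying its predecessors. Partial families are impossible by
construction: the family is the unit of removal.

## In-silico PCR

Primer sites are found by ungapped scanning of both template strands under
a per-primer mismatch budget (default 4, matching common in-silico PCR
practice). A column matches when the IUPAC sets of primer and template
intersect. Indel-tolerant placement is deliberately excluded: it would
make product coordinates ambiguous, and the fixtures rely on exact
coordinates for truth bookkeeping. Every forward/reverse pairing whose
inter-primer product length lies within the primer's bounds is emitted —
downstream dereplication absorbs redundant pairings — with products
reported primer-trimmed in forward-primer orientation (a flag retains
primers). Palindromic duplicates (same interval, same product, both
strands) are removed, keeping the plus-strand call.

## Read simulation

Reads are simulated directly from amplicons: read 1 is the 5′ prefix,
read 2 the reverse complement of the 3′ suffix, truncated to the read
length. Defaults are 500 pairs per gene copy and 130 bp reads — depths and
lengths typical of amplicon sequencing runs. Errors are i.i.d.
substitutions at a configurable rate, drawing uniformly among the three
alternative bases; qualities are a flat Phred value. Empirical,
instrument-specific error profiles (HiSeq/MiSeq models) are out of scope;
the substitution-rate model is the documented substitute, and the test
suite verifies the realized error frequency against its binomial
expectation. A mean-quality filter regenerates failing pairs with a
bounded retry budget and errors out when the configured base quality makes
the minimum unattainable.

## ASVs and ground truth

ASV derivation is exact dereplication (of amplicons, or of read pairs
merged by exact suffix/prefix overlap) — no learned error model. Support
below `min_support` is dropped; ids are assigned in decreasing-support,
then lexicographic order. Each ASV keeps the multiset of source-species
lineages that produced it. Truth is a pure function of that provenance: a
single source species gives a species-level label; multiple species give
the LCA of the sources plus a species-ambiguity flag. Ambiguity is decided
at the exact-sequence boundary — the only threshold-free one, and the one
dereplication itself defines; a near-identity mode (pool provenance across
ASVs aligning at ≥ e.g. 99%) exists behind a flag for sensitivity
analysis. Because truth never touches the classifier's reference,
exclusion experiments change predictions but not labels.

## Representative selection

Selecting a diverse species panel replaces a phylogeny-based pipeline
(alignment → tree → representative tips) with greedy max–min selection
under k-mer Jaccard distance (k = 8): the first pick maximises mean
distance to all others, each later pick maximises its minimum distance to
the chosen set, and exact ties break by a seed-derived priority. This is a
documented substitution, not a reproduction of tree-based picking; it
preserves the intent (span the diversity) at a fraction of the machinery.

## Classifiers

**Top-hit + LCA.** Align the ASV against every reference record; keep hits
with identity ≥ `min_identity` (0.97 or 1.0 in the two standard
configurations) and coverage ≥ `min_coverage` (1.0); report the LCA of the
kept lineages, with the best identity as confidence; no hit means
abstention. No e-value is modelled for the built-in aligner — e-value
filtering applies only to the external tabular adapter (default 1e-5).

**Naive Bayes over hashed k-mers.** Features are counts of every k-mer for
k in `k_range` (default 8–12) hashed into `feature_dim` buckets (default
2^18), fitted with a multinomial model, additive smoothing `alpha`
(default 0.01) and uniform or empirical priors. Hashing is non-negative
(`alternate_sign=False`): multinomial likelihoods require non-negative
counts, so collisions add. The default k-range stops at 12 rather than a
very wide sweep to keep feature extraction desk-scale; wider ranges remain
expressible in the hyperparameter grid, which `optimize_nbc` searches by
species-stratified cross-validation on mean species-level F1 (ties prefer
the narrower k-range, then the larger alpha).

*Posterior calibration.* Two corrections are applied before the
class-probability cutoff, and both are load-bearing:

1. **k-size averaging.** The per-k decompositions of one sequence are
   deterministic functions of the same bases; multiplying their
   likelihoods (the raw score) overcounts evidence by the number of k
   sizes and saturates posteriors at 0/1 on a handful of tokens. The
   pooled joint log-likelihood is therefore divided by the number of k
   sizes — the average per-k multinomial score.
2. **A uniform background hypothesis.** Classification is open-set: a
   query may come from nothing in the reference, which is precisely what
   negative controls probe. An explicit null class assigns every k-mer
   probability `1/feature_dim` and takes a 1/(C+1) prior share. A species
   accumulates posterior mass only by beating the null, so chance short
   substring matches (a random 170-mer shares a ~13 bp exact substring
   with some reference surprisingly often) stay orders of magnitude below
   any sensible cutoff, while genuine near-matches still saturate.

   With the defaults, self-classification posteriors are ≈ 1.0 and random
   or off-target queries score below 10⁻¹⁰. Large `alpha` (≳ 0.1) erodes
   the null margin — smoothed unseen-token likelihoods approach the
   uniform background — which is why 0.01 is the default.

If the best species posterior clears the cutoff (default 0.97) the species
is reported; otherwise posteriors are summed by genus, then family,
reporting at the first rank whose best aggregate clears it (a
strict-abstain mode disables backoff). Background mass never aggregates,
so out-of-scope queries abstain at every rank. Prediction depth is monotone
non-increasing in the cutoff.

**External adapters.** The 12-column tabular hit format is filtered on
e-value, identity and (when query lengths are supplied) coverage, then
LCA-reduced per query exactly like the built-in top-hit route; the
per-read-taxa format maps taxon names to lineages through the taxonomy
table. Unknown subjects or taxa are skipped with a warning and counted in
a parse report.

## Evaluation

Species-level confusion rules: TP — truth has a species and the prediction
names it; FP — the prediction names any other species, **including** a
species claim on a species-ambiguous ASV; TN — species-ambiguous truth and
no species claim; FN — species-level truth and no species claim. The FP
treatment of ambiguous ASVs is the strict reading (no true species label
exists, so any species claim is wrong); a lenient mode (claims naming one
of the colliding sources count as TP) exists behind a flag for sensitivity
analysis. Every scored ASV lands in exactly one cell.

The five scores are computed literally from the formulas in the README;
any 0/0 yields an explicit undefined marker (`None`), never an exception,
and aggregation across replicates reports median/min/max over the defined
values with a count of exclusions. The hierarchy breakdown buckets each
ASV by the deepest rank the prediction got right (correct species; wrong
species, correct genus; wrong genus, correct family; wrong family;
unassigned). Species richness counts distinct species named at species
rank per (classifier, fraction, replicate) cell, separately tallying
species absent from the truth set — pure inventions.

## Synthetic communities

Fixtures generate sequences top-down: per-family ancestral cores (random,
or mutated from one shared root when `family_divergence` is set), genus
and species levels mutated at configurable substitution rates (no indels,
so primer coordinates stay exact), every sequence embedding exact primer
sites around the variable core. Two defect types can be planted and are
listed in a manifest: cross-family exact-copy mislabels (each with its own
donor genus so conflict sets stay disjoint) and congeneric species pairs
with literally identical amplicons. Three presets mirror common community
archetypes: `balanced` (many well-separated families), `similar` (one
family of close congeners with a planted collision) and `realistic-like`
(mixed, with intra-species variants). The expected sister-species identity
under divergence rate d is (1−d)² + d²/3 ≈ 1−2d for small d, which the
suite checks on a long-core fixture.

What the fixtures do **not** emulate: real mitochondrial base composition
and codon structure, indels, chimeras, PCR efficiency/abundance bias,
variable read depth, and instrument error profiles. Passing benchmarks
therefore demonstrate the *logic* of classifiers and scoring — exclusion
behaviour, ambiguity handling, negative-control discipline — not
performance on any real reference database.

## Orchestration and determinism

`run_benchmark` executes fixture → exclusion → PCR → (reads) → ASVs →
truth → classify → evaluate for every (classifier × exclusion-plan) cell
in sorted order, writing one metrics JSON per cell, a summary TSV, a
richness TSV and a manifest sufficient to re-execute the run. A failing
cell is logged and skipped; the others continue, and callers exit non-zero
if any failed. An exclusion plan that empties the reference produces
all-abstain predictions rather than an error. Every random draw descends
from named `SeedSequence` streams, so identical configurations produce
byte-identical outputs; the suite asserts rerun equivalence at file level.

Problem sizes in the shipped tests and acceptance script (communities of
≈ 8–48 records, 100-sequence controls, 10 exclusion replicates, 10⁵
simulated bases for error-rate checks) were chosen as the smallest designs
at which every property is stable across seeds with wide margins.

## Known limitations

* The aligner is O(nm) per pair and the mislabel scan all-vs-all O(n²)
  pairs; both are sized for curated marker panels (hundreds of records),
  not genome-scale references.
* NBC posterior calibration is a modelling choice, not a probability
  guarantee; cutoffs remain operating points to be benchmarked, which is
  what the toolkit is for.
* Exact-overlap read merging assumes substitution-only errors; with indels
  (not simulated) pairs would fail to merge and be dropped with a warning.
* External-tool scoring trusts the tool's own alignment statistics;
  coverage filtering needs query lengths supplied by the caller.
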