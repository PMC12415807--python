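# ednabench

A benchmarking toolkit for taxonomic classifiers used in marker-gene
(12S/16S/COI) eDNA metabarcoding.

Environmental-DNA surveys infer which species are present in, say, a
seawater sample by amplifying a short mitochondrial marker and assigning
each denoised amplicon sequence variant (ASV) to a species with a taxonomic
classifier. How much a classifier can be trusted depends on things that are
hard to measure on real data: how it behaves when the true species is
missing from the reference database, whether it invents species for
off-target or random sequences, and how it handles amplicons that are
literally identical between species. `ednabench` makes those properties
measurable by simulating the entire experiment with known ground truth:

* **Reference curation** — load a FASTA + lineage-TSV reference panel,
  flag mislabelled records by all-vs-all self-search (overlap alignment,
  \>97% identity / 100% query coverage, LCA test, family majority vote).
* **Clade exclusion** — build reference variants with 30/50/70% of whole
  families removed, 10 replicates each, to emulate incomplete references.
* **Simulation** — native in-silico PCR with degenerate IUPAC primers and a
  per-primer mismatch budget; paired-end read simulation (500 pairs per
  gene copy, 130 bp reads by default) with i.i.d. substitution errors;
  exact dereplication into ASVs that remember which species produced them.
* **Ground truth** — an ASV from one species gets a species-level truth; an
  ASV whose sequence is shared by several species gets the LCA of its
  sources and a "no assignable species" flag.
* **Classifiers** — two built in: top-hit + lowest-common-ancestor over an
  end-gap-free overlap aligner (the BLAST-with-LCA recipe, at 97% or 100%
  identity), and a hashed k-mer multinomial naive Bayes classifier with an
  open-set class-probability cutoff and genus/family backoff. External
  tools are scored through adapters for 12-column tabular hit files and
  per-read taxon files.
* **Evaluation** — species-level confusion counts (TP: truth and prediction
  agree on the species; FP: any other species claim; TN: no claim where no
  true species label exists; FN: no claim where one was possible) and the
  five derived scores

  accuracy = (TN+TP)/(TN+TP+FP+FN), precision = TP/(TP+FP),
  recall = TP/(TP+FN), F1 = 2PR/(P+R), F0.5 = 1.25·PR/(0.25·P+R),

  plus a correct-species / correct-genus / correct-family / wrong /
  unassigned hierarchy breakdown and species-richness summaries.

Everything runs on synthetic communities generated by the built-in fixture
module (families → genera → species with controllable divergence, plus
plantable mislabels and cross-species identical amplicons), so no downloads
or external binaries are needed.

## A worked example

`examples/04_clade_exclusion_benchmark.py` builds an adversarial community
of four closely related families, removes half the families from the
classifier's reference (three random replicates) and classifies the ASVs of
the missing families:

```
replicate 0: excluded ['Fam02', 'Fam03']; 8 out-of-reference ASVs ->
    NBC wrong-species calls: 8, exact-match aligner: 0
replicate 1: excluded ['Fam02', 'Fam04']; 8 out-of-reference ASVs ->
    NBC wrong-species calls: 3, exact-match aligner: 0
replicate 2: excluded ['Fam02', 'Fam04']; 8 out-of-reference ASVs ->
    NBC wrong-species calls: 3, exact-match aligner: 0
```

Every naive-Bayes call in that listing is a false positive — the true
species is absent from the reference, but a close relative attracts a
confident wrong species name — while the exact-match (100% identity)
aligner abstains on all of them. That asymmetry is the core risk the
toolkit quantifies: k-mer classifiers trade false positives for recall when
references are incomplete, and stringent identity cutoffs do the opposite.
The other examples cover curation (`01`), simulation with ground truth
(`02`), complete-reference scoring where top-hit+LCA reaches FP = 0 and
recall = 1 (`03`), and negative controls where both classifiers make zero
species assignments on 100 random and 100 surrogate sequences (`05`).

A thin CLI mirrors the library (`ednabench fixture | curate | exclude |
pcr | simreads | asv | controls | truth | classify | evaluate | run`);
`ednabench run --config cfg.yaml` executes every
(classifier × exclusion-plan) cell and writes per-cell metrics JSON, a
combined summary TSV and a manifest that reproduces the run exactly.

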