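"""In-silico PCR, representative selection, read simulation, ASV derivation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ednabench.amplicon_sim import (
    ASV,
    Amplicon,
    Primer,
    amplify,
    derive_asvs,
    merge_pair,
    select_representatives,
    simulate_reads,
)
from ednabench.sequtils import random_dna, revcomp
from ednabench.taxonomy import Lineage

from conftest import amplify_oracle, lin

FWD = "GTCGGTAAAACTCGTGCCAGC"
REV = "CATAGTGGGGTATCTAATCCCAGTTTG"


def _primer(max_mm=0, lo=1, hi=10_000):
    return Primer("t", FWD, REV, max_mm, lo, hi)


def _embed(core: str, rng=None, flank=10) -> str:
    rng = rng or np.random.default_rng(0)
    return random_dna(rng, flank) + FWD + core + revcomp(REV) + random_dna(rng, flank)


class TestAmplify:
    def test_exact_construction_recovers_insert(self):
        rng = np.random.default_rng(1)
        core = random_dna(rng, 200)
        template = FWD + core + revcomp(REV)
        amps = amplify(template, _primer())
        assert len(amps) == 1
        assert amps[0].sequence == core
        assert (amps[0].start, amps[0].end) == (0, len(template))
        assert amps[0].strand == "+"

    def test_degenerate_primer_base_matches_template(self):
        # R (A/G) over template A counts as a match
        primer = Primer("d", "R" + FWD[1:], REV, 0, 1, 10_000)
        core = random_dna(np.random.default_rng(2), 80)
        template = "A" + FWD[1:] + core + revcomp(REV)
        amps = amplify(template, primer)
        assert [a.sequence for a in amps] == [core]

    def test_one_substitution_in_forward_needs_budget(self):
        rng = np.random.default_rng(3)
        core = random_dna(rng, 100)
        broken_fwd = ("C" if FWD[5] != "C" else "G").join([FWD[:5], FWD[6:]])
        template = broken_fwd + core + revcomp(REV)
        assert amplify(template, _primer(max_mm=0)) == []
        amps = amplify(template, _primer(max_mm=1))
        assert [a.sequence for a in amps] == [core]

    def test_product_length_bounds_enforced(self):
        core = random_dna(np.random.default_rng(4), 120)
        template = _embed(core)
        assert amplify(template, _primer(lo=121)) == []
        assert amplify(template, _primer(hi=119)) == []
        assert len(amplify(template, _primer(lo=120, hi=120))) == 1

    def test_no_site_yields_empty_list(self):
        assert amplify(random_dna(np.random.default_rng(5), 300), _primer()) == []

    def test_keep_primers_flag(self):
        core = random_dna(np.random.default_rng(6), 90)
        template = _embed(core)
        amps = amplify(template, _primer(), keep_primers=True)
        assert amps[0].sequence == FWD + core + revcomp(REV)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_exhaustive_window_oracle(self, case):
        """Random templates with noisy embedded sites agree with brute force."""
        rng = np.random.default_rng(2000 + case)
        template = random_dna(rng, 150)
        if case % 3:  # embed a degraded site pair somewhere
            fwd = list(FWD)
            for pos in rng.integers(0, len(FWD), size=case % 3):
                fwd[pos] = "ACGT"[rng.integers(4)]
            template += "".join(fwd) + random_dna(rng, 60) + revcomp(REV)
        primer = _primer(max_mm=case % 5)
        got = {a.sequence for a in amplify(template, primer)}
        assert got == amplify_oracle(template, primer)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(7)
        template = _embed(random_dna(rng, 140), rng)
        primer = _primer(max_mm=2)
        fwd_products = {a.sequence for a in amplify(template, primer)}
        rev_products = {a.sequence for a in amplify(revcomp(template), primer)}
        assert fwd_products == rev_products != set()

    def test_site_sets_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(8)
        template = _embed(random_dna(rng, 100), rng)
        # degrade the template's forward site by two substitutions
        template = template[:12] + "AA" + template[14:]
        seen = []
        for m in range(5):
            seen.append({(a.start, a.end, a.sequence)
                         for a in amplify(template, _primer(max_mm=m))})
        for small, big in itertools.pairwise(seen):
            assert small <= big


class TestSelectRepresentatives:
    def test_saturation_returns_all(self):
        seqs = [("a", "ACGTACGTACGT"), ("b", "TTTTACGTCCCC")]
        assert select_representatives(seqs, 5, seed=0) == ["a", "b"]

    def test_duplicate_pair_and_outlier(self):
        rng = np.random.default_rng(9)
        shared = random_dna(rng, 100)
        distant = random_dna(rng, 100)
        seqs = [("A", shared), ("B", shared), ("C", distant)]
        picked = select_representatives(seqs, 2, seed=1)
        assert "C" in picked
        assert len(set(picked) & {"A", "B"}) == 1
        # brute-force check: among all 2-subsets, only those containing C
        # achieve the maximal within-subset min distance
        from ednabench.amplicon_sim import _jaccard_distance, _kmer_set

        sets = {sid: _kmer_set(s, 8) for sid, s in seqs}
        best = max(
            (frozenset(pair) for pair in itertools.combinations(sets, 2)),
            key=lambda p: min(
                _jaccard_distance(sets[a], sets[b])
                for a, b in itertools.combinations(p, 2)
            ),
        )
        assert "C" in best

    def test_n_one_picks_max_mean_distance(self):
        rng = np.random.default_rng(10)
        a = random_dna(rng, 80)
        near = a[:75] + "ACGTA"
        far = random_dna(rng, 80)
        picked = select_representatives([("a", a), ("near", near), ("far", far)], 1, 0)
        assert picked == ["far"]

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            select_representatives([("a", "ACGTACGT")], 0, 0)


def _amp(seq: str, species_lin: Lineage, i: int = 0) -> Amplicon:
    return Amplicon(f"amp{i}", f"src{i}", species_lin, 0, len(seq), "+", seq)


class TestSimulateReads:
    def test_error_free_reads_reconstruct_amplicon_ends(self):
        seq = random_dna(np.random.default_rng(11), 200)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        pairs = simulate_reads(amp, n_pairs=10, read_length=130,
                               substitution_rate=0.0, seed=3)
        assert len(pairs) == 10
        for p in pairs:
            assert p.read1 == seq[:130]
            assert p.read2 == revcomp(seq)[:130]
            assert len(p.qual1) == len(p.read1)

    def test_default_depth_is_500_pairs(self):
        seq = random_dna(np.random.default_rng(12), 150)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        assert len(simulate_reads(amp, seed=1)) == 500

    def test_short_amplicon_truncates_reads(self):
        seq = random_dna(np.random.default_rng(13), 90)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        p = simulate_reads(amp, n_pairs=1, read_length=130, seed=1)[0]
        assert p.read1 == seq
        assert p.read2 == revcomp(seq)

    def test_substitution_count_within_binomial_band(self):
        """1e4 simulated bases at rate 0.01: count inside the central 99%."""
        seq = random_dna(np.random.default_rng(14), 100)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        pairs = simulate_reads(amp, n_pairs=50, read_length=100,
                               substitution_rate=0.01, seed=5)
        n_bases = 50 * 2 * 100
        errs = sum(
            sum(a != b for a, b in zip(p.read1, seq))
            + sum(a != b for a, b in zip(p.read2, revcomp(seq)))
            for p in pairs
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], n_bases, 0.01)
        assert lo <= errs <= hi

    def test_deterministic_given_seed(self):
        seq = random_dna(np.random.default_rng(15), 150)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        a = simulate_reads(amp, n_pairs=5, substitution_rate=0.05, seed=9)
        b = simulate_reads(amp, n_pairs=5, substitution_rate=0.05, seed=9)
        assert a == b

    def test_unattainable_min_quality_errors(self):
        seq = random_dna(np.random.default_rng(16), 150)
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        with pytest.raises(RuntimeError, match="min_quality"):
            simulate_reads(amp, n_pairs=1, base_quality=20, min_quality=30, seed=1)

    def test_invalid_rate_rejected(self):
        seq = "ACGT" * 30
        amp = _amp(seq, lin(order="O", family="F", genus="G", species="G s"))
        with pytest.raises(ValueError):
            simulate_reads(amp, substitution_rate=1.0, seed=0)


class TestDeriveAsvs:
    def _lineages(self):
        x = lin(order="O1", family="F1", genus="G1", species="G1 x")
        y = lin(order="O1", family="F1", genus="G1", species="G1 y")
        return x, y

    def test_dereplication_counts_support(self):
        x, y = self._lineages()
        sx = random_dna(np.random.default_rng(17), 120)
        sy = random_dna(np.random.default_rng(18), 120)
        amps = [_amp(sx, x, i) for i in range(3)] + [_amp(sy, y, 9)]
        asvs = derive_asvs(amps)
        assert len(asvs) == 2
        assert asvs[0].support == 3  # decreasing-support order
        assert [l.species for l in asvs[0].provenance] == ["G1 x"] * 3

    def test_identical_amplicons_from_two_species_collide(self):
        x, y = self._lineages()
        seq = random_dna(np.random.default_rng(19), 120)
        asvs = derive_asvs([_amp(seq, x, 0), _amp(seq, y, 1)])
        assert len(asvs) == 1
        assert {l.species for l in asvs[0].provenance} == {"G1 x", "G1 y"}

    def test_intraspecific_variants_inflate_asv_count(self):
        # one species, 3 distinct gene variants -> 3 ASVs (more ASVs than species)
        x, _ = self._lineages()
        rng = np.random.default_rng(20)
        amps = [_amp(random_dna(rng, 120), x, i) for i in range(3)]
        assert len(derive_asvs(amps)) == 3

    def test_min_support_filters(self):
        x, y = self._lineages()
        seq1 = random_dna(np.random.default_rng(21), 100)
        seq2 = random_dna(np.random.default_rng(22), 100)
        amps = [_amp(seq1, x, 0), _amp(seq1, x, 1), _amp(seq2, y, 2)]
        assert len(derive_asvs(amps, min_support=2)) == 1

    def test_support_conserved_and_count_bounded(self):
        rng = np.random.default_rng(23)
        x, _ = self._lineages()
        seqs = [random_dna(rng, 60) for _ in range(4)]
        amps = [_amp(seqs[rng.integers(4)], x, i) for i in range(20)]
        asvs = derive_asvs(amps)
        assert sum(a.support for a in asvs) == 20
        assert len(asvs) <= len({a.sequence for a in amps})

    def test_merged_reads_mode_roundtrip(self):
        x, _ = self._lineages()
        seq = random_dna(np.random.default_rng(24), 180)
        amp = _amp(seq, x)
        pairs = simulate_reads(amp, n_pairs=4, read_length=130, seed=2)
        assert merge_pair(pairs[0]) == seq
        asvs = derive_asvs(pairs, mode="dereplicate-merged-reads",
                           provenance={amp.amplicon_id: x})
        assert len(asvs) == 1
        assert asvs[0].sequence == seq
        assert asvs[0].support == 4
        assert {l.species for l in asvs[0].provenance} == {"G1 x"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            derive_asvs([])
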