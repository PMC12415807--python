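"""Built-in classifiers: top-hit+LCA, naive Bayes, and external adapters."""

import numpy as np
import pytest

from ednabench.amplicon_sim import ASV
from ednabench.classifiers import (
    classify_nbc,
    expand_grid,
    nbc_posteriors,
    optimize_nbc,
    parse_external,
    tophit_lca_classify,
    train_nbc,
)
from ednabench.sequtils import mutate, random_dna

from conftest import lin, make_db


def _asv(seq, asv_id="q1"):
    return ASV(asv_id, seq, [], 1)


def _two_genus_db(seed=0, divergence=0.2, length=200):
    """Two well-separated species per genus, two genera in one family."""
    rng = np.random.default_rng(seed)
    root = random_dna(rng, length)
    records = []
    for gi in range(2):
        g = mutate(rng, root, divergence)
        for si in range(2):
            s = mutate(rng, g, divergence)
            records.append(
                (f"g{gi}s{si}", s,
                 lin(order="O1", family="F1", genus=f"G{gi}", species=f"G{gi} s{si}"))
            )
    return make_db(records)


class TestTophitLca:
    def test_unique_exact_hit_gives_species(self):
        db = _two_genus_db()
        query = db.records[0].sequence
        res = tophit_lca_classify(_asv(query), db, min_identity=0.97)
        assert res.species == "G0 s0"
        assert res.confidence == 1.0

    def test_two_congeneric_hits_reduce_to_genus(self):
        rng = np.random.default_rng(1)
        base = random_dna(rng, 100)
        sib = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        db = make_db([
            ("s1", base, lin(order="O", family="F", genus="G", species="G a")),
            ("s2", sib, lin(order="O", family="F", genus="G", species="G b")),
        ])
        # query one substitution from each: 99% identity to both
        query = base[:20] + ("T" if base[20] not in "T" else "G") + base[21:]
        res = tophit_lca_classify(_asv(query), db, min_identity=0.97)
        assert res.rank == "genus"
        assert res.lineage.genus == "G"

    def test_below_cutoff_abstains_and_exact_only_at_100(self):
        rng = np.random.default_rng(2)
        base = random_dna(rng, 100)
        query = mutate(rng, base, 0.05)  # ~95% identity
        db = make_db([("s1", base, lin(order="O", family="F", genus="G", species="G a"))])
        res = tophit_lca_classify(_asv(query), db, min_identity=0.97)
        assert res.rank is None
        assert res.confidence < 0.97
        # the stringent configuration classifies only exact matches
        assert tophit_lca_classify(_asv(base), db, min_identity=1.0).species == "G a"
        one_sub = base[:10] + ("A" if base[10] != "A" else "C") + base[11:]
        assert tophit_lca_classify(_asv(one_sub), db, min_identity=1.0).rank is None

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            tophit_lca_classify(_asv("ACGT" * 10), make_db([]))


class TestNbc:
    def test_self_classification_on_divergent_species(self):
        db = _two_genus_db(divergence=0.2)
        model = train_nbc(db, feature_dim=2**14)
        for rec in db.records:
            res = classify_nbc(model, _asv(rec.sequence, rec.seqid))
            assert res.species == rec.lineage.species
            assert res.confidence > 0.97

    def test_identical_training_sequences_split_posterior(self):
        seq = random_dna(np.random.default_rng(3), 200)
        db = make_db([
            ("a", seq, lin(order="O", family="F", genus="G", species="G a")),
            ("b", seq, lin(order="O", family="F", genus="G", species="G b")),
        ])
        model = train_nbc(db, feature_dim=2**14)
        post = nbc_posteriors(model, seq)
        assert post[0] == pytest.approx(post[1])
        assert post.sum() == pytest.approx(1.0, abs=1e-6)  # background ~ 0
        assert post[0] == pytest.approx(0.5, abs=1e-6)

    def test_congener_collision_resolves_at_genus_via_backoff(self):
        seq = random_dna(np.random.default_rng(4), 200)
        db = make_db([
            ("a", seq, lin(order="O", family="F", genus="G", species="G a")),
            ("b", seq, lin(order="O", family="F", genus="G", species="G b")),
        ])
        model = train_nbc(db, feature_dim=2**14)
        res = classify_nbc(model, _asv(seq))
        assert res.rank == "genus"
        assert res.confidence == pytest.approx(1.0)
        strict = classify_nbc(model, _asv(seq), backoff=False)
        assert strict.rank is None

    def test_large_alpha_flattens_posteriors(self):
        db = _two_genus_db()
        model = train_nbc(db, alpha=1e6, fit_prior=False, feature_dim=2**12)
        post = nbc_posteriors(model, db.records[0].sequence)
        # smoothing washes out all evidence: every species equally likely
        assert post == pytest.approx([post[0]] * 4, rel=1e-3)
        assert post.max() < 0.5

    def test_prediction_depth_monotone_in_cutoff(self):
        db = _two_genus_db(divergence=0.05)  # close species: soft posteriors
        model = train_nbc(db, feature_dim=2**14)
        rng = np.random.default_rng(5)
        depth = {"species": 5, "genus": 4, "family": 3, None: 0}
        for rec in db.records[:2]:
            noisy = mutate(rng, rec.sequence, 0.03)
            depths = [
                depth[classify_nbc(model, _asv(noisy), prob_cutoff=c).rank]
                for c in (0.5, 0.9, 0.97, 0.999, 1.0 - 1e-12)
            ]
            assert depths == sorted(depths, reverse=True)

    def test_invalid_parameters_rejected(self):
        db = _two_genus_db()
        with pytest.raises(ValueError):
            train_nbc(db, k_range=(9, 8))
        with pytest.raises(ValueError):
            train_nbc(db, alpha=0.0)


class TestOptimizeNbc:
    def _db(self):
        # 3 sequences per species so 3-fold CV is stratifiable
        rng = np.random.default_rng(6)
        root = random_dna(rng, 150)
        records = []
        for si in range(3):
            s = mutate(rng, root, 0.25)
            for ci in range(3):
                records.append(
                    (f"s{si}c{ci}", mutate(rng, s, 0.01),
                     lin(order="O", family="F", genus=f"G{si}", species=f"G{si} sp"))
                )
        return make_db(records)

    def test_single_point_grid(self):
        db = self._db()
        model, report = optimize_nbc(db, [{"k_range": (8, 10), "feature_dim": 2**12}],
                                     folds=3, seed=1)
        assert len(report) == 1
        assert model.k_range == (8, 10)

    def test_sane_point_beats_crippled_point(self):
        db = self._db()
        grid = [
            {"k_range": (1, 1), "feature_dim": 2**12},
            {"k_range": (8, 12), "feature_dim": 2**12},
        ]
        model, report = optimize_nbc(db, grid, folds=3, seed=2)
        assert model.k_range == (8, 12)
        scores = {tuple(p["k_range"]): p["mean_f1"] for p in report}
        assert scores[(8, 12)] > scores[(1, 1)]

    def test_deterministic_given_seed(self):
        db = self._db()
        grid = expand_grid(k_range=[(6, 8), (8, 12)], alpha=[0.001, 0.1],
                           feature_dim=[2**12])
        _, r1 = optimize_nbc(db, grid, folds=3, seed=3)
        _, r2 = optimize_nbc(db, grid, folds=3, seed=3)
        assert r1 == r2

    def test_rare_species_held_out_with_warning(self):
        db = self._db()
        rng = np.random.default_rng(7)
        extra = make_db(
            [(r.seqid, r.sequence, r.lineage) for r in db.records]
            + [("lone", random_dna(rng, 150),
                lin(order="O", family="F", genus="GZ", species="GZ solo"))]
        )
        with pytest.warns(UserWarning, match="fewer than"):
            optimize_nbc(extra, [{"k_range": (8, 10), "feature_dim": 2**12}],
                         folds=3, seed=4)


class TestParseExternal:
    HEADER_DB = None

    def _db(self):
        rng = np.random.default_rng(8)
        return make_db([
            ("r1", random_dna(rng, 120),
             lin(order="O", family="F1", genus="Ga", species="Ga x")),
            ("r2", random_dna(rng, 120),
             lin(order="O", family="F1", genus="Ga", species="Ga y")),
            ("r3", random_dna(rng, 120),
             lin(order="O", family="F1", genus="Gb", species="Gb z")),
        ])

    @staticmethod
    def _row(q, s, pident, evalue=1e-20):
        return f"{q}\t{s}\t{pident}\t120\t1\t0\t1\t120\t1\t120\t{evalue}\t200"

    def test_single_passing_row_gives_species(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row("q1", "r1", 99.0) + "\n")
        results, report = parse_external(path, "tabular-hits", self._db())
        assert len(results) == 1
        assert results[0].species == "Ga x"
        assert report["skipped"] == 0

    def test_rows_spanning_two_genera_reduce_to_family(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join([
            self._row("q1", "r1", 99.0),
            self._row("q1", "r3", 98.5),
        ]) + "\n")
        results, _ = parse_external(path, "tabular-hits", self._db())
        assert results[0].rank == "family"
        assert results[0].lineage.family == "F1"

    def test_identity_and_evalue_filters(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join([
            self._row("q1", "r1", 90.0),          # below identity cutoff
            self._row("q2", "r1", 99.0, evalue=1),  # above e-value cutoff
        ]) + "\n")
        results, _ = parse_external(path, "tabular-hits", self._db())
        assert results == []

    def test_empty_file_gives_empty_results(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        results, report = parse_external(path, "tabular-hits", self._db())
        assert results == []
        assert report["rows"] == 0

    def test_unknown_subject_skipped_with_warning(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row("q1", "missing", 99.0) + "\n")
        with pytest.warns(UserWarning, match="unknown subject"):
            results, report = parse_external(path, "tabular-hits", self._db())
        assert results == []
        assert report["skipped"] == 1

    def test_per_read_taxa_dialect(self, tmp_path):
        path = tmp_path / "taxa.tsv"
        path.write_text("read1\tGa x\nread2\tGa\nread3\tNosuchtaxon\n")
        with pytest.warns(UserWarning, match="unknown taxon"):
            results, report = parse_external(path, "per-read-taxa", self._db())
        by_id = {r.asv_id: r for r in results}
        assert by_id["read1"].species == "Ga x"
        assert by_id["read2"].rank == "genus"
        assert report["skipped"] == 1

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            parse_external(path, "nope", self._db())
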