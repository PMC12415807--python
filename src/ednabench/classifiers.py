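"""Built-in taxonomic classifiers and external-output adapters.

Two classifier families are implemented natively:

* ``tophit_lca_classify`` — align the query against every reference record,
  keep hits above an identity/coverage threshold and report the lowest
  common ancestor of their lineages (the classic BLAST-with-LCA recipe; at
  100% identity it becomes the stringent exact-match configuration).
* ``train_nbc`` / ``classify_nbc`` — a multinomial naive Bayes classifier
  over hashed k-mer counts with a class-probability cutoff and rank backoff
  (sum posteriors per genus, then family, when no species is confident).

``parse_external`` scores third-party tools from their output files without
re-implementing them: a 12-column tabular hit format is filtered and
LCA-reduced exactly like the built-in top-hit route, and a per-read taxon
format is mapped to lineages by name.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.naive_bayes import MultinomialNB

from .align import AlignmentResult, align_semiglobal
from .amplicon_sim import ASV
from .refdb import ReferenceDB
from .taxonomy import Lineage, lca

__all__ = [
    "AlignmentResult",
    "align_semiglobal",
    "ClassificationResult",
    "NBCModel",
    "tophit_lca_classify",
    "train_nbc",
    "classify_nbc",
    "nbc_posteriors",
    "optimize_nbc",
    "parse_external",
    "expand_grid",
]


@dataclass(frozen=True)
class ClassificationResult:
    """A prediction truncated at the deepest confident rank.

    An empty lineage means the classifier abstained (confidence below every
    rank's cutoff); ``confidence`` is then the best score it saw, which by
    construction sits below the cutoff.
    """

    asv_id: str
    lineage: Lineage
    confidence: float
    classifier: str
    params: str = field(default="", compare=False)

    @property
    def species(self) -> str | None:
        return self.lineage.species

    @property
    def rank(self) -> str | None:
        return self.lineage.deepest_rank


def _digest(**params) -> str:
    text = ",".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha1(text.encode()).hexdigest()[:8]


# ---------------------------------------------------------------------------
# top-hit + LCA


def tophit_lca_classify(
    asv: ASV,
    db: ReferenceDB,
    min_identity: float = 0.97,
    min_coverage: float = 1.0,
) -> ClassificationResult:
    """Classify one ASV by LCA over all sufficiently good reference hits.

    Identity uses a >=-cutoff (the conventional "97% identity" style
    threshold); coverage likewise.  No passing hit yields an abstention with
    the best observed identity as confidence.
    """
    if not db.records:
        raise ValueError("reference DB is empty")
    name = "tophit_lca"
    params = _digest(min_identity=min_identity, min_coverage=min_coverage)
    hits: list[Lineage] = []
    best = 0.0
    for rec in db.records:
        res = align_semiglobal(asv.sequence, rec.sequence, rec.seqid)
        if res.coverage >= min_coverage:
            best = max(best, res.identity)
        if res.identity >= min_identity and res.coverage >= min_coverage:
            hits.append(rec.lineage)
    if not hits:
        return ClassificationResult(asv.asv_id, Lineage(()), best, name, params)
    return ClassificationResult(asv.asv_id, lca(hits), best, name, params)


# ---------------------------------------------------------------------------
# naive Bayes over hashed k-mer counts


@dataclass
class NBCModel:
    """A trained multinomial naive Bayes k-mer classifier."""

    k_range: tuple[int, int]
    feature_dim: int
    alpha: float
    fit_prior: bool
    seed: int
    vectorizer: HashingVectorizer
    nb: MultinomialNB
    class_lineages: dict[str, Lineage]  # species name -> full lineage

    @property
    def classes(self) -> list[str]:
        return list(self.nb.classes_)

    @property
    def params_digest(self) -> str:
        return _digest(
            k_range=self.k_range,
            feature_dim=self.feature_dim,
            alpha=self.alpha,
            fit_prior=self.fit_prior,
        )


def train_nbc(
    db: ReferenceDB,
    k_range: tuple[int, int] = (8, 12),
    feature_dim: int = 2**18,
    alpha: float = 0.01,
    fit_prior: bool = False,
    seed: int = 0,
) -> NBCModel:
    """Train the naive Bayes classifier on a reference DB.

    Features are counts of every k-mer for k in ``k_range`` hashed into
    ``feature_dim`` buckets (collisions add; hashing is unsigned so counts
    stay valid multinomial evidence).  One class per species; additive
    smoothing ``alpha``; priors empirical when ``fit_prior`` else uniform.
    Training is deterministic — ``seed`` only names the model for
    reproducibility manifests.
    """
    kmin, kmax = k_range
    if kmin > kmax or kmin < 1:
        raise ValueError("k_range must satisfy 1 <= kmin <= kmax")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    by_species: dict[str, Lineage] = {}
    docs, labels = [], []
    for rec in db.records:
        sp = rec.lineage.species
        if sp is None:
            raise ValueError(f"record {rec.seqid} has no species; cannot train")
        by_species[sp] = rec.lineage.truncate("species")
        docs.append(rec.sequence)
        labels.append(sp)
    vec = HashingVectorizer(
        analyzer="char",
        ngram_range=(kmin, kmax),
        n_features=feature_dim,
        alternate_sign=False,
        lowercase=False,
        norm=None,
    )
    X = vec.transform(docs)
    nb = MultinomialNB(alpha=alpha, fit_prior=fit_prior)
    nb.fit(X, labels)
    return NBCModel(
        (kmin, kmax), feature_dim, alpha, fit_prior, seed, vec, nb, by_species
    )


def nbc_posteriors(model: NBCModel, sequence: str) -> np.ndarray:
    """Open-set species posteriors for one query sequence.

    Two calibrations are applied to the raw multinomial score before
    normalizing, both needed for the class-probability cutoff to behave as
    an abstention mechanism:

    * **k-size averaging** — features pool every k in the model's range,
      but the per-k decompositions of one sequence are deterministic
      functions of the same bases, not independent observations; the
      pooled joint log-likelihood is divided by the number of k sizes
      (averaging the per-k multinomial scores rather than multiplying
      them), which stops posteriors collapsing to 0/1 on a handful of
      tokens.
    * **a uniform background hypothesis** — classification is open-set: a
      query may come from nothing in the reference (negative controls are
      exactly this case).  An explicit null class assigns every k-mer
      probability 1/feature_dim, so a species only accumulates posterior
      mass by beating the null, not merely its sibling classes; chance
      short substring matches then stay far below any sensible cutoff.

    Returns the per-species posterior vector (model class order).  It sums
    to <= 1; the remainder is the background mass, which never counts
    toward any rank's confidence.
    """
    X = model.vectorizer.transform([sequence])
    n_sizes = model.k_range[1] - model.k_range[0] + 1
    jll = (X @ model.nb.feature_log_prob_.T).ravel() / n_sizes
    bg_jll = float(X.sum()) * -np.log(model.feature_dim) / n_sizes
    n_classes = len(model.nb.classes_)
    # priors: background takes a 1/(C+1) share; species keep their ratios
    logits = np.append(
        jll + model.nb.class_log_prior_ + np.log(n_classes / (n_classes + 1)),
        bg_jll + np.log(1.0 / (n_classes + 1)),
    )
    logits -= logits.max()
    post = np.exp(logits)
    post /= post.sum()
    return post[:-1]


def classify_nbc(
    model: NBCModel,
    asv: ASV,
    prob_cutoff: float = 0.97,
    backoff: bool = True,
) -> ClassificationResult:
    """Predict a lineage for one ASV from species posteriors.

    If the best species posterior reaches ``prob_cutoff`` the species is
    reported; otherwise posteriors are aggregated by genus and then family,
    reporting at the first rank whose best aggregate clears the cutoff
    (``backoff=False`` disables this and abstains instead).  Confidence is
    the accepted aggregate probability, or the best species posterior on
    abstention.
    """
    post = nbc_posteriors(model, asv.sequence)
    species = model.classes
    name = "nbc"
    params = model.params_digest + f",cutoff={prob_cutoff}"

    best_i = int(np.argmax(post))
    if post[best_i] >= prob_cutoff:
        lin = model.class_lineages[species[best_i]]
        return ClassificationResult(asv.asv_id, lin, float(post[best_i]), name, params)
    if backoff:
        for rank in ("genus", "family"):
            agg: dict[Lineage, float] = {}
            for sp, p in zip(species, post):
                key = model.class_lineages[sp].truncate(rank)
                agg[key] = agg.get(key, 0.0) + p
            top = max(agg, key=lambda k: (agg[k], str(k)))
            if agg[top] >= prob_cutoff:
                return ClassificationResult(asv.asv_id, top, float(agg[top]), name, params)
    return ClassificationResult(asv.asv_id, Lineage(()), float(post[best_i]), name, params)


def optimize_nbc(
    db: ReferenceDB,
    grid: list[dict] | None = None,
    folds: int = 3,
    seed: int = 0,
    prob_cutoff: float = 0.97,
) -> tuple[NBCModel, list[dict]]:
    """Grid-search NBC hyperparameters by stratified cross-validation.

    Each grid point is a dict of ``train_nbc`` keyword overrides.  Folds are
    stratified over species; species with fewer sequences than ``folds`` are
    held out of CV with a warning.  The score is the mean species-level F1
    of held-out predictions (abstentions count as false negatives, wrong
    species as false positives).  Ties prefer the smaller k-range width,
    then the larger alpha.  Returns the winning model retrained on all data
    plus a per-grid-point report.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(db.records):
        by_species.setdefault(rec.lineage.species, []).append(i)
    usable = {sp: idx for sp, idx in by_species.items() if len(idx) >= folds}
    skipped = sorted(set(by_species) - set(usable))
    if skipped:
        warnings.warn(
            f"{len(skipped)} species with fewer than {folds} sequences held out of CV: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no species has enough sequences for cross-validation")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    fold_of = {}
    for sp, idx in sorted(usable.items()):
        perm = rng.permutation(len(idx))
        for pos, j in enumerate(perm):
            fold_of[idx[j]] = pos % folds

    report = []
    for point in grid:
        f1s = []
        for fold in range(folds):
            train_idx = [i for i, f in fold_of.items() if f != fold]
            test_idx = [i for i, f in fold_of.items() if f == fold]
            if not train_idx or not test_idx:
                continue
            sub = ReferenceDB(db.marker, [db.records[i] for i in sorted(train_idx)])
            model = train_nbc(sub, seed=seed, **point)
            tp = fp = fn = 0
            for i in sorted(test_idx):
                rec = db.records[i]
                probe = ASV(rec.seqid, rec.sequence, [rec.lineage], 1)
                pred = classify_nbc(model, probe, prob_cutoff=prob_cutoff)
                if pred.species == rec.lineage.species:
                    tp += 1
                elif pred.species is not None:
                    fp += 1
                else:
                    fn += 1
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec_ = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec_ / (prec + rec_) if prec + rec_ else 0.0
            f1s.append(f1)
        report.append({**point, "mean_f1": float(np.mean(f1s)) if f1s else 0.0})

    def sort_key(entry: dict):
        kr = entry.get("k_range", (8, 12))
        return (-entry["mean_f1"], kr[1] - kr[0], -entry.get("alpha", 0.01))

    best = min(report, key=sort_key)
    winner = {k: v for k, v in best.items() if k != "mean_f1"}
    return train_nbc(db, seed=seed, **winner), report


def expand_grid(**lists) -> list[dict]:
    """Cartesian product of keyword lists into ``optimize_nbc`` grid points."""
    keys = sorted(lists)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(lists[k] for k in keys))]


# ---------------------------------------------------------------------------
# external classifier outputs

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_external(
    path,
    dialect: str,
    db: ReferenceDB,
    min_identity: float = 0.97,
    min_coverage: float = 1.0,
    max_evalue: float = 1e-5,
    query_lengths: dict[str, int] | None = None,
    taxon_map: dict[str, Lineage] | None = None,
) -> tuple[list[ClassificationResult], dict]:
    """Convert an external tool's output file into classification results.

    ``tabular-hits``: the standard 12-column tab-separated hit table
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore).  Rows are filtered on e-value, identity, and — when
    ``query_lengths`` provides the query length — coverage, then reduced to
    one LCA prediction per query, exactly as ``tophit_lca_classify``.

    ``per-read-taxa``: lines of ``read_id<TAB>taxon``; taxon names resolve
    through ``taxon_map`` (default: every name in the DB's lineages).
    Unknown subjects/taxa are skipped with a warning and counted in the
    returned parse report.
    """
    import pandas as pd

    report = {"rows": 0, "skipped": 0, "queries": 0}
    results: list[ClassificationResult] = []
    lineage_of = {rec.seqid: rec.lineage for rec in db.records}

    if dialect == "tabular-hits":
        try:
            table = pd.read_csv(path, sep="\t", header=None, names=_HIT_COLUMNS, comment="#")
        except pd.errors.EmptyDataError:
            return [], report
        report["rows"] = len(table)
        by_query: dict[str, list[tuple[Lineage, float]]] = {}
        for row in table.itertuples(index=False):
            lin = lineage_of.get(row.sseqid)
            if lin is None:
                warnings.warn(f"unknown subject id {row.sseqid!r}; row skipped", stacklevel=2)
                report["skipped"] += 1
                continue
            if row.evalue > max_evalue or row.pident / 100.0 < min_identity:
                continue
            if query_lengths is not None:
                qlen = query_lengths.get(row.qseqid)
                if qlen and (abs(row.qend - row.qstart) + 1) / qlen < min_coverage:
                    continue
            by_query.setdefault(row.qseqid, []).append((lin, row.pident / 100.0))
        for qid in sorted(by_query):
            hits = by_query[qid]
            best = max(p for _, p in hits)
            results.append(
                ClassificationResult(qid, lca([l for l, _ in hits]), best, "external-tabular")
            )
        report["queries"] = len(results)
        return results, report

    if dialect == "per-read-taxa":
        if taxon_map is None:
            taxon_map = {}
            for lin in lineage_of.values():
                for rank, name in lin.items():
                    cut = lin.truncate(rank)
                    if name not in taxon_map or cut.depth > taxon_map[name].depth:
                        taxon_map[name] = cut
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                report["rows"] += 1
                read_id, _, taxon = line.partition("\t")
                lin = taxon_map.get(taxon.strip())
                if lin is None:
                    warnings.warn(f"unknown taxon {taxon!r}; record skipped", stacklevel=2)
                    report["skipped"] += 1
                    continue
                results.append(ClassificationResult(read_id, lin, 1.0, "external-taxa"))
        report["queries"] = len(results)
        return results, report

    raise ValueError(f"unknown dialect {dialect!r}")
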