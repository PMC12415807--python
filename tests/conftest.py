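"""Shared fixtures: tiny reference databases and independent oracles."""

from __future__ import annotations

import pytest

from ednabench.fixtures import FixtureSpec, make_toy_refdb
from ednabench.refdb import ReferenceDB, RefRecord
from ednabench.sequtils import bases_match, revcomp
from ednabench.taxonomy import Lineage


def lin(cls="Toyclassia", order=None, family=None, genus=None, species=None) -> Lineage:
    names = [cls]
    for name in (order, family, genus, species):
        if name is None:
            break
        names.append(name)
    return Lineage(tuple(names))


@pytest.fixture
def lutjanid_lineages() -> dict[str, Lineage]:
    base = ("Actinopteri", "Perciformes", "Lutjanidae", "Lutjanus")
    return {
        "argentimaculatus": Lineage(base + ("Lutjanus argentimaculatus",)),
        "jocu": Lineage(base + ("Lutjanus jocu",)),
        "other_family": Lineage(
            ("Actinopteri", "Perciformes", "Haemulidae", "Plectorhinchus",
             "Plectorhinchus vittatus")
        ),
        "other_order": Lineage(
            ("Actinopteri", "Beryciformes", "Holocentridae", "Sargocentron",
             "Sargocentron rubrum")
        ),
    }


@pytest.fixture
def balanced_db():
    """A diverse many-family toy DB (no planted defects)."""
    db, manifest = make_toy_refdb(FixtureSpec(
        n_families=6, genera_per_family=2, species_per_genus=2,
        genus_divergence=0.12, species_divergence=0.05, seed=7,
    ))
    return db, manifest


def make_db(records: list[tuple[str, str, Lineage]], marker: str = "12S") -> ReferenceDB:
    return ReferenceDB(marker, [RefRecord(*r) for r in records])


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def lca_oracle(lineages) -> tuple[str, ...]:
    """Longest common prefix of the rank-name paths."""
    out = []
    for column in zip(*[l.names for l in lineages]):
        if all(name == column[0] for name in column):
            out.append(column[0])
        else:
            break
    return tuple(out)


def amplify_oracle(template: str, primer) -> set[str]:
    """Exhaustive window scan on both strands; returns product sequences."""
    products: set[str] = set()
    fwd = primer.forward
    rev_probe = revcomp(primer.reverse)
    for strand_seq in (template, revcomp(template)):
        def sites(probe):
            hits = []
            for i in range(len(strand_seq) - len(probe) + 1):
                mm = sum(
                    not bases_match(probe[j], strand_seq[i + j])
                    for j in range(len(probe))
                )
                if mm <= primer.max_mismatches:
                    hits.append(i)
            return hits

        for fs in sites(fwd):
            for rs in sites(rev_probe):
                if rs < fs + len(fwd):
                    continue
                insert = strand_seq[fs + len(fwd):rs]
                if primer.min_length <= len(insert) <= primer.max_length:
                    products.add(insert)
    return products


def align_oracle(query: str, subject: str) -> tuple[int, float]:
    """Plain quadratic overlap-alignment DP; returns (score, identity).

    Same scoring scheme and tie preferences as the library aligner but a
    completely naive implementation (python lists, explicit 3-way max, no
    vectorization or prefix-max folding).
    """
    n, m = len(query), len(subject)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            sc = 1 if bases_match(query[i - 1], subject[j - 1]) else -1
            row[j] = max(prev[j - 1] + sc, prev[j] - 1, row[j - 1] - 1)
    j_best = max(range(m + 1), key=lambda j: H[n][j])
    i_best = max(range(n + 1), key=lambda i: H[i][m])
    if H[i_best][m] > H[n][j_best]:
        i, j = i_best, m
    else:
        i, j = n, j_best
    score = H[i][j]
    matches = columns = 0
    while i > 0 and j > 0:
        hit = bases_match(query[i - 1], subject[j - 1])
        if H[i][j] == H[i - 1][j - 1] + (1 if hit else -1):
            matches += hit
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    identity = matches / columns if columns else 0.0
    return score, identity
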