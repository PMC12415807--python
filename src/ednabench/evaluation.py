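"""Species-level scoring of classifier predictions against simulated truth.

The confusion definitions are the strict species-level ones used for
metabarcoding benchmarks:

* **TP** — the truth has a species label and the classifier predicts it;
* **FP** — the classifier names any species other than the truth species,
  or names a species where the truth is species-ambiguous (no true species
  label exists);
* **TN** — the truth is species-ambiguous and the classifier names no
  species;
* **FN** — the truth has a species label but the classifier names none.

From TP/FP/TN/FN the five standard scores follow: accuracy
(TN+TP)/(TN+TP+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2PR/(P+R) and F0.5 = (1+0.5²)PR/(0.5²P+R), the last weighting
precision over recall.  Degenerate 0/0 ratios yield an explicit
undefined marker (None), never an exception.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classifiers import ClassificationResult
from .truthing import TruthLabel

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "score_predictions",
    "compute_metrics",
    "hierarchical_breakdown",
    "species_richness",
    "aggregate_metrics",
    "BREAKDOWN_BUCKETS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """The five scores; None marks an undefined (0/0) metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    f05: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f05": self.f05,
        }


def score_predictions(
    truths: Mapping[str, TruthLabel],
    predictions: Iterable[ClassificationResult],
    ambiguous_match_is_tp: bool = False,
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Score predictions against truth, one verdict per ASV.

    ``ambiguous_match_is_tp`` switches on the lenient mode in which a
    species call on a species-ambiguous ASV counts as TP when the named
    species is one of the colliding sources; the default (strict) mode
    scores every species claim without a true species label as FP.
    Truth and prediction ids must coincide; orphans raise with a listing.
    """
    preds = {p.asv_id: p for p in predictions}
    orphans_t = sorted(set(truths) - set(preds))
    orphans_p = sorted(set(preds) - set(truths))
    if orphans_t or orphans_p:
        raise ValueError(
            f"ASV id mismatch: {len(orphans_t)} truth-only {orphans_t[:5]}, "
            f"{len(orphans_p)} prediction-only {orphans_p[:5]}"
        )

    rows = []
    tally = Counter()
    for asv_id in sorted(truths):
        t, p = truths[asv_id], preds[asv_id]
        pred_sp = p.species
        if t.species_ambiguous:
            if pred_sp is None:
                verdict = "TN"
            elif ambiguous_match_is_tp and pred_sp in t.source_species:
                # lenient mode: naming one of the colliding sources counts
                verdict = "TP"
            else:
                verdict = "FP"
        else:
            if pred_sp is None:
                verdict = "FN"
            elif pred_sp == t.species:
                verdict = "TP"
            else:
                verdict = "FP"
        tally[verdict] += 1
        rows.append(
            {
                "asv_id": asv_id,
                "truth_rank": t.rank or "none",
                "truth_species": t.species or "",
                "truth_genus": t.lineage.genus or "",
                "truth_family": t.lineage.family or "",
                "pred_rank": p.rank or "none",
                "pred_species": pred_sp or "",
                "pred_genus": p.lineage.genus or "",
                "pred_family": p.lineage.family or "",
                "confidence": p.confidence,
                "verdict": verdict,
                "genus_match": bool(p.lineage.genus) and p.lineage.genus == t.lineage.genus,
                "family_match": bool(p.lineage.family) and p.lineage.family == t.lineage.family,
            }
        )
    counts = ConfusionCounts(tally["TP"], tally["FP"], tally["TN"], tally["FN"])
    return counts, pd.DataFrame(rows)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the five score formulas; 0/0 becomes the None marker."""
    if c.total == 0:
        raise ValueError("compute_metrics requires at least one scored ASV")
    accuracy = _ratio(c.tn + c.tp, c.total)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None:
        f1 = f05 = None
    else:
        f1 = _ratio(2 * precision * recall, precision + recall)
        f05 = _ratio((1 + 0.5**2) * precision * recall, 0.5**2 * precision + recall)
    return MetricSet(accuracy, precision, recall, f1, f05)


BREAKDOWN_BUCKETS = (
    "correct_species",
    "wrong_species_correct_genus",
    "wrong_genus_correct_family",
    "wrong_family",
    "unassigned",
)


def hierarchical_breakdown(verdicts: pd.DataFrame) -> dict[str, int]:
    """Place each scored ASV into exactly one hierarchy bucket.

    Buckets mirror the usual correct-species / correct-genus /
    correct-family / wrong / unassigned split of benchmark figures: a
    prediction lands in the deepest bucket whose rank it got right.
    """
    counts = dict.fromkeys(BREAKDOWN_BUCKETS, 0)
    for row in verdicts.itertuples(index=False):
        if row.pred_rank == "none":
            bucket = "unassigned"
        elif row.pred_species and row.pred_species == row.truth_species:
            bucket = "correct_species"
        elif row.pred_genus and row.pred_genus == row.truth_genus:
            bucket = "wrong_species_correct_genus"
        elif row.pred_family and row.pred_family == row.truth_family:
            bucket = "wrong_genus_correct_family"
        else:
            bucket = "wrong_family"
        counts[bucket] += 1
    return counts


def species_richness(
    predictions_by_cell: Mapping[tuple, Iterable[ClassificationResult]],
    truth_species: set[str] | None = None,
) -> pd.DataFrame:
    """Distinct species detected per (classifier, fraction, replicate) cell.

    ``richness`` counts unique species named at species rank;
    ``false_positive_species`` counts those absent from ``truth_species``
    (species the community never contained — pure inventions).
    """
    rows = []
    for key in sorted(predictions_by_cell, key=str):
        preds = list(predictions_by_cell[key])
        named = {p.species for p in preds if p.species}
        fp_species = (
            sorted(named - truth_species) if truth_species is not None else []
        )
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                "cell": "/".join(str(k) for k in key_t),
                "richness": len(named),
                "false_positive_species": len(fp_species) if truth_species is not None else None,
                "invented_species": ";".join(fp_species),
            }
        )
    return pd.DataFrame(rows)


def aggregate_metrics(metric_sets: Iterable[MetricSet]) -> dict[str, dict]:
    """Median / min / max per metric across replicates.

    Undefined values are excluded from the order statistics; the number of
    exclusions is reported alongside so they are never silently dropped.
    """
    out: dict[str, dict] = {}
    sets = list(metric_sets)
    for name in ("accuracy", "precision", "recall", "f1", "f05"):
        vals = [getattr(m, name) for m in sets]
        defined = [v for v in vals if v is not None]
        out[name] = {
            "median": float(np.median(defined)) if defined else None,
            "min": float(min(defined)) if defined else None,
            "max": float(max(defined)) if defined else None,
            "n": len(defined),
            "undefined": len(vals) - len(defined),
        }
    return out
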