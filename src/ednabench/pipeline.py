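"""End-to-end benchmark orchestration.

``run_benchmark`` wires the whole chain together for every
(dataset × classifier × exclusion plan) cell:

    fixture/refdb → exclusion variants → in-silico PCR → (reads) → ASVs
    → truth → classify → evaluate

Cells are independent and executed in sorted key order; a failing cell is
logged and skipped while the others continue.  Every seed and parameter
lands in a manifest so a run can be re-executed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .amplicon_sim import Primer, amplify_db, derive_asvs, simulate_reads
from .classifiers import (
    ClassificationResult,
    classify_nbc,
    tophit_lca_classify,
    train_nbc,
)
from .taxonomy import Lineage
from .evaluation import (
    compute_metrics,
    hierarchical_breakdown,
    score_predictions,
    species_richness,
)
from .fixtures import TOY_PRIMER, make_toy_refdb, preset
from .refdb import ReferenceDB, exclude_families, load_refdb
from .truthing import truth_table

log = logging.getLogger("ednabench")

__all__ = ["RunConfig", "run_benchmark"]


def _default_classifiers() -> list[dict]:
    return [
        {"name": "tophit97", "type": "tophit", "min_identity": 0.97, "min_coverage": 1.0},
        {"name": "tophit100", "type": "tophit", "min_identity": 1.0, "min_coverage": 1.0},
        {
            "name": "nbc",
            "type": "nbc",
            "k_range": [8, 12],
            "feature_dim": 65536,
            "alpha": 0.01,
            "fit_prior": False,
            "prob_cutoff": 0.97,
        },
    ]


@dataclass
class RunConfig:
    """Everything a benchmark run needs, YAML-round-trippable."""

    preset: str = "balanced"
    seed: int = 42
    marker: str = "12S"
    refdb_fasta: str | None = None  # overrides the preset when given
    refdb_lineages: str | None = None
    primer: dict | None = None
    fractions: list[float] = field(default_factory=lambda: [0.3, 0.5, 0.7])
    replicates: int = 10
    simulate_reads: bool = False
    n_pairs: int = 500
    read_length: int = 130
    substitution_rate: float = 0.0
    base_quality: int = 35
    min_quality: int = 0
    min_support: int = 1
    classifiers: list[dict] = field(default_factory=_default_classifiers)
    ambiguous_match_is_tp: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_primer(self) -> Primer:
        if self.primer is None:
            return TOY_PRIMER
        return Primer(**self.primer)


def _cell_tag(name: str, fraction: float, replicate: int) -> str:
    return f"{name}_f{int(round(fraction * 100)):03d}_r{replicate:02d}"


def run_benchmark(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every benchmark cell and write the report bundle.

    Writes one metrics JSON per cell under ``outdir/cells/``, a combined
    ``summary.tsv``, and ``manifest.json`` recording the full configuration.
    Returns the in-memory report; ``report['failed_cells']`` is non-empty
    when any cell aborted (callers should exit non-zero then).
    """
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    primer = config.resolve_primer()

    # --- reference database (the query community source) ---
    if config.refdb_fasta:
        db = load_refdb(config.refdb_fasta, config.refdb_lineages, config.marker)
        manifest_fixture = {"source": "user", "fasta": str(config.refdb_fasta)}
    else:
        spec = preset(config.preset, seed=config.seed)
        db, fixture_manifest = make_toy_refdb(spec)
        manifest_fixture = {"source": f"preset:{config.preset}", **fixture_manifest}
    log.info("refdb - loaded %d records, %d families", len(db), len(db.families))

    # --- simulate the query side once (truth never depends on exclusions) ---
    amplicons = amplify_db(db, primer)
    log.info("pcr - %d amplicons from %d records", len(amplicons), len(db))
    if config.simulate_reads:
        pairs = []
        prov = {}
        for i, amp in enumerate(amplicons):
            pairs.extend(
                simulate_reads(
                    amp,
                    n_pairs=config.n_pairs,
                    read_length=config.read_length,
                    substitution_rate=config.substitution_rate,
                    base_quality=config.base_quality,
                    min_quality=config.min_quality,
                    seed=config.seed + i,
                )
            )
            prov[amp.amplicon_id] = amp.source_lineage
        asvs = derive_asvs(
            pairs, mode="dereplicate-merged-reads",
            min_support=config.min_support, provenance=prov,
        )
    else:
        asvs = derive_asvs(amplicons, min_support=config.min_support)
    truths = truth_table(asvs)
    log.info("asv - %d ASVs, %d species-ambiguous",
             len(asvs), sum(t.species_ambiguous for t in truths.values()))

    # --- exclusion plans: fraction 0.0 is the complete-reference baseline ---
    plans = [(0.0, 0)] + [
        (f, r) for f in config.fractions for r in range(config.replicates)
    ]
    truth_species = {t.species for t in truths.values() if t.species}

    summary_rows: list[dict] = []
    failed: list[str] = []
    richness_cells: dict[tuple, list] = {}
    for fraction, replicate in plans:
        sub_db, plan = exclude_families(db, fraction, config.seed, replicate)
        for spec_c in sorted(config.classifiers, key=lambda c: c["name"]):
            tag = _cell_tag(spec_c["name"], fraction, replicate)
            try:
                if not sub_db.records:
                    # exclusion emptied the reference: nothing can classify
                    preds = [
                        ClassificationResult(a.asv_id, Lineage(()), 0.0,
                                             spec_c["name"])
                        for a in asvs
                    ]
                elif spec_c["type"] == "tophit":
                    preds = [
                        tophit_lca_classify(
                            a, sub_db,
                            min_identity=spec_c.get("min_identity", 0.97),
                            min_coverage=spec_c.get("min_coverage", 1.0),
                        )
                        for a in asvs
                    ]
                elif spec_c["type"] == "nbc":
                    model = train_nbc(
                        sub_db,
                        k_range=tuple(spec_c.get("k_range", (8, 12))),
                        feature_dim=spec_c.get("feature_dim", 2**16),
                        alpha=spec_c.get("alpha", 0.01),
                        fit_prior=spec_c.get("fit_prior", False),
                        seed=config.seed,
                    )
                    preds = [
                        classify_nbc(model, a, prob_cutoff=spec_c.get("prob_cutoff", 0.97))
                        for a in asvs
                    ]
                else:
                    raise ValueError(f"unknown classifier type {spec_c['type']!r}")

                counts, verdicts = score_predictions(
                    truths, preds, ambiguous_match_is_tp=config.ambiguous_match_is_tp
                )
                metrics = compute_metrics(counts)
                breakdown = hierarchical_breakdown(verdicts)
                richness_cells[(spec_c["name"], fraction, replicate)] = preds
                named = {p.species for p in preds if p.species}
                cell = {
                    "cell": tag,
                    "classifier": spec_c["name"],
                    "fraction": fraction,
                    "replicate": replicate,
                    "excluded_families": list(plan.excluded),
                    "counts": {"tp": counts.tp, "fp": counts.fp,
                               "tn": counts.tn, "fn": counts.fn},
                    "metrics": metrics.as_dict(),
                    "breakdown": breakdown,
                    "richness": {
                        "detected_species": len(named),
                        "false_positive_species": len(named - truth_species),
                    },
                }
                with open(outdir / "cells" / f"{tag}.json", "w", encoding="utf-8") as fh:
                    json.dump(cell, fh, indent=2, sort_keys=True)
                    fh.write("\n")
                summary_rows.append(
                    {
                        "cell": tag,
                        "classifier": spec_c["name"],
                        "fraction": fraction,
                        "replicate": replicate,
                        **{k: v for k, v in cell["counts"].items()},
                        **{k: ("" if v is None else f"{v:.6f}")
                           for k, v in cell["metrics"].items()},
                        "detected_species": cell["richness"]["detected_species"],
                        "false_positive_species": cell["richness"]["false_positive_species"],
                    }
                )
                log.info("evaluate - cell %s done: %s", tag, cell["counts"])
            except Exception:  # noqa: BLE001 - cell isolation is the contract
                log.exception("evaluate - cell %s FAILED", tag)
                failed.append(tag)

    # --- combined outputs ---
    import pandas as pd

    summary = pd.DataFrame(summary_rows)
    summary_path = outdir / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    richness = species_richness(richness_cells, truth_species)
    richness.to_csv(outdir / "richness.tsv", sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "fixture": manifest_fixture,
        "n_asvs": len(asvs),
        "n_cells": len(summary_rows),
        "failed_cells": failed,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "summary": summary,
        "manifest": manifest,
        "failed_cells": failed,
        "truths": truths,
        "asvs": asvs,
    }
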