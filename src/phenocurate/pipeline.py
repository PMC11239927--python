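"""End-to-end curation runs: read -> prune -> fit -> flag -> remove -> re-fit
-> BLUEs -> heritability -> summaries, with a machine-readable manifest.

Traits are processed independently; one trait's model failure is recorded
in the manifest and does not abort the others.  The manifest accounts for
every input record in exactly one of {fitted, pruned, flagged,
rejected-at-parse}.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .heritability import heritability_pipeline
from .mixed_model import ModelSpec, compute_blues, reml_fit, prune_sparse
from .outliers import correct_outliers
from .records import Dataset, TRAITS, read_assay_table, write_outputs
from .summaries import provenance_table, records_by_decade, regeneration_distribution

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one curation run."""

    input_path: str
    growth_habit: str
    output_dir: str
    traits: tuple[str, ...] = TRAITS
    spec: ModelSpec = field(default_factory=ModelSpec)
    alpha: float = 0.05
    studentized: bool = False
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def curate_dataset(
    dataset: Dataset, config: RunConfig, outdir: Path
) -> dict:
    """Run the per-trait curation stages on an in-memory dataset."""
    manifest: dict = {
        "package": "phenocurate",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {
            "input_path": str(config.input_path),
            "growth_habit": config.growth_habit,
            "traits": list(config.traits),
            "alpha": config.alpha,
            "studentized": config.studentized,
            "model_spec": dataclasses.asdict(config.spec),
        },
        "traits": {},
    }
    pr = dataset.parse_report
    if pr is not None:
        manifest["parse_report"] = {
            "rows_read": pr.rows_read,
            "records_produced": pr.records_produced,
            "producing_rows": pr.producing_rows,
            "empty_rows": pr.empty_rows,
            "rejected_rows": len(pr.rejected_rows),
            "rejected_cells": len(pr.rejected_cells),
            "duplicate_records": pr.duplicate_records,
        }

    for trait in config.traits:
        entry: dict = {}
        manifest["traits"][trait] = entry
        n_input = int((dataset.df["trait"] == trait).sum())
        entry["n_records_input"] = n_input
        if n_input == 0:
            entry["status"] = "no records"
            continue
        enhanced, report = correct_outliers(
            dataset, trait, config.spec, config.alpha, config.studentized
        )
        entry["outlier_report"] = report.summary_row()
        entry["accounting"] = {
            "input": n_input,
            "pruned_away": n_input - report.n_records_pruned,
            "flagged": report.n_outliers,
            "fitted": report.corrected_size,
        }
        if enhanced is None:
            entry["status"] = "fit failed"
            entry["failure"] = report.failure
            continue
        try:
            pruned2, prune2 = prune_sparse(enhanced, trait, config.spec)
            refit = reml_fit(
                pruned2, trait, dataclasses.replace(config.spec, genotype_role="fixed")
            )
            refit.n_records_pruned = prune2.n_removed
            blues = compute_blues(refit)
            paths = write_outputs(refit, report, blues, outdir)
            entry["outputs"] = {k: str(p.name) for k, p in paths.items()}
            entry["n_blues"] = int(len(blues))
        except (ValueError, RuntimeError) as exc:
            entry["status"] = "refit failed"
            entry["failure"] = str(exc)
            continue
        herit = {}
        for stage, ds in (("original", dataset), ("enhanced", enhanced)):
            hres = heritability_pipeline(ds, trait, config.spec, dataset_stage=stage)
            herit[stage] = {
                "fit_ok": hres.fit_ok,
                "sigma2_G": hres.sigma2_G,
                "sigma2_e_mean": hres.sigma2_e_mean,
                "mean_years": hres.mean_years,
                "h2": hres.h2,
                "diagnosis": hres.diagnosis,
            }
        entry["heritability"] = herit
        entry["status"] = "ok"
    return manifest


def run_curation(config: RunConfig) -> dict:
    """Full curation run from an assay file on disk; returns the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = read_assay_table(config.input_path, config.growth_habit)
    manifest = curate_dataset(dataset, config, outdir)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def summarize_dataset(dataset: Dataset) -> dict:
    """Descriptive summaries (provenance, decade counts, regeneration histograms)."""
    out = {
        "provenance": provenance_table(dataset).to_frame().to_dict(orient="records"),
        "records_by_decade": records_by_decade(dataset).to_dict(orient="records"),
        "regeneration": {
            trait: regeneration_distribution(dataset, trait) for trait in TRAITS
        },
    }
    return out
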