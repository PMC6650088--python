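"""End-to-end orchestration: preprocess → priors → infer → calibrate → call →
analyze, with plain TSV/JSON artifacts at every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .types import Cohort, FormatError, GeneSetCollection
from . import io as tci_io
from .preprocess import removals_frame
from .priors import alteration_stats, cohort_priors, priors_frame
from .engine import compute_scores, infer_cohort, models_frame
from .calibration import attach_pvalues, build_null, permute_degs_within_tissue
from .calling import (
    call_cohort,
    calls_frame,
    conserved_edges,
    summarize_sga_fis,
    target_degs,
    target_sets,
)
from .analysis import pairwise_target_overlap, hallmark_coverage

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every field maps to a CLI flag."""

    sga_path: str = ""
    deg_path: str = ""
    tumor_map_path: str = ""
    mutsig_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "tci_out"
    prior_scheme: str = "uniform"
    theta0: float = 0.1
    mu_floor: float = 1e-6
    alpha1: float = 1.0
    alpha0: float = 1.0
    n_perm: int = 20
    seed: int = 0
    min_targets: int = 5
    alpha: float = 0.05
    min_tumors: int = 30
    min_call_rate: float = 0.25
    target_min_abs: int = 50
    target_min_frac: float = 0.20
    permute_degs: bool = False  # analyze a within-tissue permuted dataset

    def validate(self) -> None:
        if not (0 < self.theta0 < 1):
            raise ValueError("theta0 must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_perm < 1 or self.min_targets < 1:
            raise ValueError("n_perm and min_targets must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_cohort(config: RunConfig) -> Cohort:
    sga = tci_io.read_binary_matrix(config.sga_path)
    deg = tci_io.read_binary_matrix(config.deg_path)
    tissue = tci_io.read_tumor_map(config.tumor_map_path)
    return Cohort(sga=sga, deg=deg, tissue=tissue)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the full pipeline; returns (and writes) the run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cohort is None:
            cohort = load_cohort(config)
        if config.permute_degs:
            cohort = Cohort(
                sga=cohort.sga,
                deg=permute_degs_within_tissue(cohort.deg, cohort.tissue, config.seed + 7),
                tissue=cohort.tissue,
            )

        stage = "priors"
        mutsig = tci_io.read_mutsig(config.mutsig_path) if config.mutsig_path else None
        inputs = alteration_stats(cohort.sga, mutsig)
        priors = cohort_priors(
            cohort, config.prior_scheme, inputs, config.theta0, config.mu_floor
        )
        priors_frame(priors).to_csv(out / "priors.tsv", sep="\t", index=False)

        stage = "infer"
        scores = compute_scores(cohort.sga, cohort.deg, config.alpha1, config.alpha0)
        models = infer_cohort(cohort, priors, scores=scores)

        stage = "calibrate"
        table = build_null(
            cohort,
            priors,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha1=config.alpha1,
            alpha0=config.alpha0,
        )
        tci_io.write_json(table.to_dict(), out / "calibration.json")
        attach_pvalues(models, table)
        models_frame(models).to_csv(out / "edges.tsv", sep="\t", index=False)

        stage = "call"
        calls = call_cohort(models, config.min_targets, config.alpha)
        calls_frame(calls).to_csv(out / "sgafi_calls.tsv", sep="\t", index=False)
        summary = summarize_sga_fis(calls, cohort.sga, config.min_tumors, config.min_call_rate)
        summary.to_csv(out / "sgafi_summary.tsv", sep="\t", index_label="sga")
        targets = target_degs(
            calls, summary, config.target_min_abs, config.target_min_frac
        )
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)

        stage = "analyze"
        sets = target_sets(targets)
        universe = set().union(*sets.values()) if sets else set()
        overlap = pairwise_target_overlap(sets, max(len(universe), 1))
        overlap.to_csv(out / "overlap_network.tsv", sep="\t", index=False)
        if config.gmt_path:
            genesets = tci_io.read_gmt(config.gmt_path)
            hallmark_coverage(sets, genesets).to_csv(
                out / "coverage.tsv", sep="\t", index_label="sga"
            )
        conserved = conserved_edges(models, cohort.tissue)
        pd.DataFrame(sorted(conserved), columns=["sga", "deg"]).to_csv(
            out / "conserved_edges.tsv", sep="\t", index=False
        )

        stage = "summary"
        run_summary = {
            "version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "prior_scheme": config.prior_scheme,
            "theta0": config.theta0,
            "thresholds": {
                "min_targets": config.min_targets,
                "alpha": config.alpha,
                "min_tumors": config.min_tumors,
                "min_call_rate": config.min_call_rate,
            },
            "n_tumors": cohort.n_tumors,
            "n_sga_genes": len(cohort.sga.genes),
            "n_deg_genes": len(cohort.deg.genes),
            "n_sga_events": int(cohort.sga.values.sum()),
            "n_deg_events": int(cohort.deg.values.sum()),
            "n_sga_fi_calls": len(calls),
            "n_significant_sga_fis": int(summary["significant"].sum()),
            "n_target_edges": int(len(targets)),
            "n_overlap_pairs": int(len(overlap)),
            "n_conserved_edges": len(conserved),
        }
        tci_io.write_json(run_summary, out / "summary.json")
        return run_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
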