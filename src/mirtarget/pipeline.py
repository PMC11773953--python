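"""End-to-end orchestration: simulate -> features -> labels -> ensemble -> validate.

The pipeline mirrors the discovery workflow on synthetic data: per-cohort
correlation features are computed from the generated panels, labels come
from the *training* tier of planted interactions only, the consensus
ensemble proposes significant pairs from the negative class, and the
held-out tier plays the role of the validation databases.  A handful of
perturbation experiments are then simulated for miRNAs with called pairs to
produce DEG-overlap and direction-concordance reports.

Every artifact is a TSV under ``out_dir`` plus a ``manifest.json`` recording
all seeds and parameters; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as _io
from ._util import pct, stage_seed
from .ensemble import EnsembleConfig, call_significant, metric_summary, run_suite
from .features import build_feature_table
from .labeling import InteractionDB, assign_labels
from .simulate import SimulationConfig, simulate_panels, simulate_perturbation
from .validation import (
    ConcordanceEntry,
    deg_ttest,
    direction_concordance,
    overlap_stats,
    validation_rate,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

# fixed stage-seed offsets, recorded in the manifest
SIM_OFFSET = 0
ENSEMBLE_OFFSET = 1_000
PERTURBATION_OFFSET = 2_000


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    min_coexpressing: int = 10
    max_missing: int = 3
    alpha: float = 0.05
    # Operating point for the headline validation rate: the middle of the
    # downsampling grid with the 70% frequency fraction, unless overridden.
    report_rate: float | None = None
    report_threshold: int | None = None
    n_perturbations: int = 3
    perturbation_shift: float = 2.0
    perturbation_n_per_group: int = 20

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raise ValueError(f"{path}: config must set 'out_dir'")
        sim = SimulationConfig(**_tupled(raw.pop("simulation", {})))
        ens = EnsembleConfig(**_tupled(raw.pop("ensemble", {})))
        return cls(simulation=sim, ensemble=ens, **raw)


def _tupled(section: Mapping[str, Any]) -> dict[str, Any]:
    """YAML lists -> tuples so they slot into the frozen config dataclasses."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in section.items()}


@dataclass
class PipelineReport:
    out_dir: str
    n_pairs: int
    positive_fraction_pct: float
    significant_grid: pd.DataFrame
    validation_grid: pd.DataFrame
    report_validation_pct: float
    concordance_pct: int | None
    manifest_path: str


def _dataclass_dict(obj) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, Mapping):
            v = dict(v)
        out[f.name] = v
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage in order, writing all intermediate artifacts.

    Stage seeds are derived from ``config.seed`` by fixed offsets so the
    whole run is reproducible from the one global seed.
    """
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    sim_config = config.simulation.with_(seed=stage_seed(config.seed, SIM_OFFSET))
    panels, truth = simulate_panels(sim_config)

    # -- features ----------------------------------------------------------
    table = build_feature_table(
        panels,
        max_missing=config.max_missing,
        min_coexpressing=config.min_coexpressing,
    )
    _io.write_feature_table(table, os.path.join(out_dir, "features.tsv"))

    # -- labels (training tier only; held-out tier stays unseen) -----------
    train_db = InteractionDB(
        "synthetic-training", "training", frozenset(truth.pairs_by_tier("training"))
    )
    heldout_db = InteractionDB(
        "synthetic-heldout", "validation", frozenset(truth.pairs_by_tier("heldout"))
    )
    labels = assign_labels(table, [train_db])
    _io.write_labels(labels, os.path.join(out_dir, "labels.tsv"))

    # -- ensemble ----------------------------------------------------------
    ens_config = dataclasses.replace(
        config.ensemble, base_seed=stage_seed(config.seed, ENSEMBLE_OFFSET)
    )
    result = run_suite(table, labels, ens_config)
    _io.write_consensus_counts(result, os.path.join(out_dir, "consensus_counts.tsv"))
    metric_summary(result).to_csv(os.path.join(out_dir, "metrics_per_rate.tsv"), sep="\t")

    # -- held-out database validation over the whole grid -------------------
    grid = result.grid()
    val_grid = grid.copy().astype(object)
    for rate in grid.index:
        for t in grid.columns:
            sig = call_significant(result, rate, t)
            if sig:
                v = validation_rate(sig, [heldout_db], [train_db])
                val_grid.at[rate, t] = f"{len(sig)}/{v.rate_pct}%"
            else:
                val_grid.at[rate, t] = "0/-"
    grid.to_csv(os.path.join(out_dir, "significant_grid.tsv"), sep="\t")
    val_grid.to_csv(os.path.join(out_dir, "validation_grid.tsv"), sep="\t")

    rates = ens_config.downsample_rates
    report_rate = config.report_rate or rates[(len(rates) - 1) // 2]
    report_threshold = config.report_threshold or round(0.7 * ens_config.n_models)
    significant = call_significant(result, report_rate, report_threshold)
    if significant:
        report_pct = validation_rate(significant, [heldout_db], [train_db]).rate_pct
    else:
        report_pct = float("nan")

    # -- perturbation validation -------------------------------------------
    sig_mirnas = sorted({m for m, _ in significant})[: config.n_perturbations]
    overlap_rows = []
    entries: list[ConcordanceEntry] = []
    pert_seed = stage_seed(config.seed, PERTURBATION_OFFSET)
    for j, mirna in enumerate(sig_mirnas):
        # pick the cohort where this miRNA regulates the most planted targets
        per_cohort = {
            c: len(truth.targets_of(mirna, cohort=c)) for c in truth.cohorts
        }
        cohort = max(sorted(per_cohort), key=per_cohort.get)
        ds = simulate_perturbation(
            truth,
            mirna,
            cohort,
            n_per_group=config.perturbation_n_per_group,
            shift=config.perturbation_shift,
            seed=pert_seed + j,
        )
        _io.write_perturbation_tsv(
            ds, os.path.join(out_dir, f"perturbation_{mirna}_{cohort}.tsv")
        )
        deg = deg_ttest(ds, alpha=config.alpha)
        degs = deg.degs()
        predicted = {g for m, g in significant if m == mirna}
        known = {g for m, g in truth.pairs_by_tier("training") if m == mirna}
        if predicted and known:
            overlap_rows.append(overlap_stats(predicted, known, degs, dataset_id=mirna))
        for gene in sorted(predicted & degs):
            entries.append(
                ConcordanceEntry(
                    mirna=mirna,
                    gene=gene,
                    cohort_context=cohort,
                    direction=deg.direction_of(gene),
                    correlation_sign=table.correlation_sign(mirna, gene, cohort),
                )
            )

    if overlap_rows:
        pd.DataFrame([dataclasses.asdict(r) for r in overlap_rows]).to_csv(
            os.path.join(out_dir, "deg_overlap.tsv"), sep="\t", index=False
        )
    concordance_pct: int | None = None
    usable = [e for e in entries if e.correlation_sign is not None]
    if usable:
        summary = direction_concordance(entries)
        concordance_pct = summary.percentage
        pd.DataFrame([dataclasses.asdict(e) for e in entries]).to_csv(
            os.path.join(out_dir, "concordance.tsv"), sep="\t", index=False
        )

    # -- manifest -----------------------------------------------------------
    manifest = {
        "global_seed": config.seed,
        "stage_seeds": {
            "simulation": sim_config.seed,
            "ensemble": ens_config.base_seed,
            "perturbation": pert_seed,
        },
        "simulation": _dataclass_dict(sim_config),
        "ensemble": _dataclass_dict(ens_config),
        "min_coexpressing": config.min_coexpressing,
        "max_missing": config.max_missing,
        "alpha": config.alpha,
        "n_pairs": table.n_pairs,
        "n_dropped_pairs": table.n_dropped,
        "positive_fraction_pct": labels.positive_fraction_pct,
        "report_rate": report_rate,
        "report_threshold": report_threshold,
        "report_validation_pct": None if report_pct != report_pct else report_pct,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineReport(
        out_dir=out_dir,
        n_pairs=table.n_pairs,
        positive_fraction_pct=labels.positive_fraction_pct,
        significant_grid=grid,
        validation_grid=val_grid,
        report_validation_pct=report_pct,
        concordance_pct=concordance_pct,
        manifest_path=manifest_path,
    )
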