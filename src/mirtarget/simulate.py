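"""Synthetic multi-cohort expression data with planted miRNA->gene effects.

Real pipelines of this kind start from per-cancer-type miRNA and mRNA
expression matrices, curated interaction databases, and perturbation
experiments.  This module generates stand-ins for all three with *known*
planted structure, so that every downstream stage (correlation features,
labelling, the consensus ensemble, validation) can be exercised and its
recovery of the planted truth measured.

Model: expression lives directly on a non-negative log scale where 0 means
"not expressed".  Each miRNA is drawn from a Gaussian clipped at zero.  A
planted pair (m, g, sign) that is active in a cohort contributes
``sign * beta * (m - mean_m)`` to gene g on top of the gene's baseline and
Gaussian noise; in inactive cohorts, and for all non-planted pairs, gene and
miRNA are independent.  Dropout then zeroes entries independently to mimic
non-expression.  Planted pairs are partitioned into three disjoint tiers:

* ``training``      -- appear in the training interaction database,
* ``heldout``       -- appear only in the validation database,
* ``undiscovered``  -- appear in no database (true but unreported).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import MirtargetError

__all__ = [
    "SimulationConfig",
    "PlantedPair",
    "GroundTruth",
    "ExpressionPanel",
    "PerturbationDataset",
    "simulate_panels",
    "simulate_perturbation",
    "write_fixtures",
]

TIERS = ("training", "heldout", "undiscovered")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale study: 8 cohorts of 120 samples,
    60 miRNAs x 300 genes (18,000 candidate pairs), 500 planted pairs split
    250/120/130 over the training/heldout/undiscovered tiers.
    """

    n_cohorts: int = 8
    n_mirnas: int = 60
    n_genes: int = 300
    samples_per_cohort: int | tuple[int, int] = 120
    effect_size_range: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.4
    dropout_prob: float = 0.1
    frac_active_cohorts: float = 0.75
    n_planted_training: int = 250
    n_planted_heldout: int = 120
    n_planted_undiscovered: int = 130
    frac_positive_sign: float = 0.5
    seed: int = 0
    # marginal-distribution knobs (log-expression units)
    mirna_mean: float = 4.0
    mirna_sd: float = 1.0
    baseline_range: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts,
            "n_mirnas": self.n_mirnas,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name in ("n_planted_training", "n_planted_heldout", "n_planted_undiscovered"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_prob", "frac_active_cohorts", "frac_positive_sign"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.effect_size_range
        if lo < 0 or hi < lo:
            raise ValueError("effect_size_range must be 0 <= lo <= hi")
        if self.n_planted_total > self.n_mirnas * self.n_genes:
            raise ValueError(
                "planted pair count exceeds the miRNA x gene universe "
                f"({self.n_planted_total} > {self.n_mirnas * self.n_genes})"
            )
        spc = self.samples_per_cohort
        if isinstance(spc, int):
            if spc < 2:
                raise ValueError("samples_per_cohort must be >= 2")
        else:
            lo, hi = spc
            if lo < 2 or hi < lo:
                raise ValueError("samples_per_cohort range must be 2 <= lo <= hi")

    @property
    def n_planted_total(self) -> int:
        return (
            self.n_planted_training
            + self.n_planted_heldout
            + self.n_planted_undiscovered
        )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PlantedPair:
    mirna: str
    gene: str
    sign: int  # +1 or -1
    active_cohorts: frozenset[str]
    tier: str  # training | heldout | undiscovered
    effect_size: float


@dataclass(frozen=True)
class GroundTruth:
    """The planted regulatory structure underlying a simulated panel set."""

    mirnas: tuple[str, ...]
    genes: tuple[str, ...]
    cohorts: tuple[str, ...]
    pairs: tuple[PlantedPair, ...]

    def pairs_by_tier(self, tier: str) -> set[tuple[str, str]]:
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
        return {(p.mirna, p.gene) for p in self.pairs if p.tier == tier}

    def targets_of(self, mirna: str, cohort: str | None = None) -> dict[str, int]:
        """Planted target genes of ``mirna`` (optionally restricted to a cohort),
        mapped to their planted sign."""
        if mirna not in self.mirnas:
            raise KeyError(f"unknown miRNA id {mirna!r}")
        out: dict[str, int] = {}
        for p in self.pairs:
            if p.mirna != mirna:
                continue
            if cohort is not None and cohort not in p.active_cohorts:
                continue
            out[p.gene] = p.sign
        return out


@dataclass
class ExpressionPanel:
    """One cohort's paired miRNA and gene expression matrices.

    Both matrices are samples x features on a non-negative log scale with
    0 meaning not expressed, and share the sample axis.
    """

    cohort_id: str
    mirna: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mirna.index.equals(self.genes.index):
            raise ValueError(f"panel {self.cohort_id}: sample axes differ")
        for name, df in (("mirna", self.mirna), ("gene", self.genes)):
            values = df.to_numpy()
            if not np.isfinite(values).all():
                raise ValueError(f"panel {self.cohort_id}: non-finite {name} values")
            if (values < 0).any():
                raise ValueError(f"panel {self.cohort_id}: negative {name} values")

    @property
    def samples(self) -> list[str]:
        return list(self.mirna.index)


@dataclass
class PerturbationDataset:
    """Two-group (control vs miRNA-perturbed) gene expression experiment."""

    mirna_id: str
    cohort_context: str
    control: pd.DataFrame  # samples x genes
    treated: pd.DataFrame  # samples x genes
    perturbation: str = "overexpression"  # or "knockdown"

    def __post_init__(self) -> None:
        if not self.control.columns.equals(self.treated.columns):
            raise ValueError("control and treated matrices must share the gene axis")
        if len(self.control) < 2 or len(self.treated) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.perturbation not in ("overexpression", "knockdown"):
            raise ValueError(f"unknown perturbation {self.perturbation!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.control.columns)


def _cohort_ids(n: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"mir-{i + 1}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _plant_pairs(config: SimulationConfig, rng: np.random.Generator,
                 mirnas: Sequence[str], genes: Sequence[str],
                 cohorts: Sequence[str]) -> tuple[PlantedPair, ...]:
    total = config.n_planted_total
    flat = rng.choice(config.n_mirnas * config.n_genes, size=total, replace=False)
    signs = np.where(rng.random(total) < config.frac_positive_sign, 1, -1)
    betas = rng.uniform(*config.effect_size_range, size=total)
    n_active = max(1, round(config.frac_active_cohorts * config.n_cohorts))
    tiers = (
        ["training"] * config.n_planted_training
        + ["heldout"] * config.n_planted_heldout
        + ["undiscovered"] * config.n_planted_undiscovered
    )
    pairs = []
    for idx, sign, beta, tier in zip(flat, signs, betas, tiers):
        m, g = divmod(int(idx), config.n_genes)
        active = frozenset(
            cohorts[c] for c in rng.choice(config.n_cohorts, size=n_active, replace=False)
        )
        pairs.append(
            PlantedPair(mirnas[m], genes[g], int(sign), active, tier, float(beta))
        )
    return tuple(pairs)


def simulate_panels(config: SimulationConfig) -> tuple[list[ExpressionPanel], GroundTruth]:
    """Generate one expression panel per cohort plus the planted ground truth.

    Fully deterministic given ``config.seed``: the same config yields
    identical panels and :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    cohorts = _cohort_ids(config.n_cohorts)
    mirnas = _mirna_ids(config.n_mirnas)
    genes = _gene_ids(config.n_genes)

    pairs = _plant_pairs(config, rng, mirnas, genes, cohorts)
    truth = GroundTruth(tuple(mirnas), tuple(genes), tuple(cohorts), pairs)

    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    mirna_pos = {m: i for i, m in enumerate(mirnas)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    panels = []
    for cohort in cohorts:
        if isinstance(config.samples_per_cohort, int):
            n_s = config.samples_per_cohort
        else:
            lo, hi = config.samples_per_cohort
            n_s = int(rng.integers(lo, hi + 1))
        samples = [f"{cohort}-S{j + 1:04d}" for j in range(n_s)]

        mi = np.maximum(
            rng.normal(config.mirna_mean, config.mirna_sd, size=(n_s, config.n_mirnas)),
            0.0,
        )
        ge = baselines[None, :] + rng.normal(0.0, config.noise_sd,
                                             size=(n_s, config.n_genes))
        for p in pairs:
            if cohort not in p.active_cohorts:
                continue
            mcol = mi[:, mirna_pos[p.mirna]]
            ge[:, gene_pos[p.gene]] += p.sign * p.effect_size * (mcol - config.mirna_mean)
        ge = np.maximum(ge, 0.0)

        if config.dropout_prob > 0:
            mi = np.where(rng.random(mi.shape) < config.dropout_prob, 0.0, mi)
            ge = np.where(rng.random(ge.shape) < config.dropout_prob, 0.0, ge)

        panels.append(
            ExpressionPanel(
                cohort_id=cohort,
                mirna=pd.DataFrame(mi, index=samples, columns=mirnas),
                genes=pd.DataFrame(ge, index=samples, columns=genes),
            )
        )
    return panels, truth


def simulate_perturbation(
    truth: GroundTruth,
    mirna: str,
    cohort_context: str,
    n_per_group: int = 20,
    shift: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    perturbation: str = "overexpression",
    baseline: float = 6.0,
) -> PerturbationDataset:
    """Simulate a two-group perturbation experiment for one miRNA.

    Under overexpression, every planted target of ``mirna`` active in
    ``cohort_context`` is shifted by ``sign * shift`` log-units in the
    treated group; under knockdown the shift is mirrored.  Non-targets are
    untouched, so at shift 0 the experiment is an exact null.
    """
    if mirna not in truth.mirnas:
        raise KeyError(f"unknown miRNA id {mirna!r}")
    if cohort_context not in truth.cohorts:
        raise KeyError(f"unknown cohort id {cohort_context!r}")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    direction = 1.0 if perturbation == "overexpression" else -1.0

    rng = np.random.default_rng(seed)
    genes = list(truth.genes)
    targets = truth.targets_of(mirna, cohort=cohort_context)

    control = baseline + rng.normal(0.0, noise_sd, size=(n_per_group, len(genes)))
    treated = baseline + rng.normal(0.0, noise_sd, size=(n_per_group, len(genes)))
    for gene, sign in targets.items():
        treated[:, genes.index(gene)] += direction * sign * shift
    control = np.maximum(control, 0.0)
    treated = np.maximum(treated, 0.0)

    c_idx = [f"ctrl-{i + 1:03d}" for i in range(n_per_group)]
    t_idx = [f"trt-{i + 1:03d}" for i in range(n_per_group)]
    return PerturbationDataset(
        mirna_id=mirna,
        cohort_context=cohort_context,
        control=pd.DataFrame(control, index=c_idx, columns=genes),
        treated=pd.DataFrame(treated, index=t_idx, columns=genes),
        perturbation=perturbation,
    )


def write_fixtures(
    panels: Iterable[ExpressionPanel],
    truth: GroundTruth,
    datasets: Iterable[PerturbationDataset],
    out_dir: str | os.PathLike,
) -> dict[str, list[str]]:
    """Write panels, tiered interaction databases and perturbation tables as TSV.

    Layout under ``out_dir``::

        panels/<cohort>_mirna.tsv, panels/<cohort>_genes.tsv
        databases/<tier>.tsv                (two columns: mirna, gene)
        perturbations/<mirna>_<cohort>.tsv  (sample, group, then gene columns)
        ground_truth.tsv

    Everything round-trips losslessly through :mod:`mirtarget.io` readers.
    """
    from . import io as _io  # local import: io depends on types defined here

    out_dir = os.fspath(out_dir)
    paths: dict[str, list[str]] = {"panels": [], "databases": [], "perturbations": []}

    panel_dir = os.path.join(out_dir, "panels")
    os.makedirs(panel_dir, exist_ok=True)
    for panel in panels:
        for kind, df in (("mirna", panel.mirna), ("genes", panel.genes)):
            path = os.path.join(panel_dir, f"{panel.cohort_id}_{kind}.tsv")
            _io.write_expression_tsv(df, path)
            paths["panels"].append(path)

    db_dir = os.path.join(out_dir, "databases")
    os.makedirs(db_dir, exist_ok=True)
    for tier in TIERS:
        path = os.path.join(db_dir, f"{tier}.tsv")
        rows = sorted(truth.pairs_by_tier(tier))
        _io.write_interaction_tsv(rows, path)
        paths["databases"].append(path)

    pert_dir = os.path.join(out_dir, "perturbations")
    os.makedirs(pert_dir, exist_ok=True)
    for ds in datasets:
        path = os.path.join(pert_dir, f"{ds.mirna_id}_{ds.cohort_context}.tsv")
        _io.write_perturbation_tsv(ds, path)
        paths["perturbations"].append(path)

    gt_path = os.path.join(out_dir, "ground_truth.tsv")
    gt = pd.DataFrame(
        {
            "mirna": [p.mirna for p in truth.pairs],
            "gene": [p.gene for p in truth.pairs],
            "sign": [p.sign for p in truth.pairs],
            "tier": [p.tier for p in truth.pairs],
            "effect_size": [p.effect_size for p in truth.pairs],
            "active_cohorts": [",".join(sorted(p.active_cohorts)) for p in truth.pairs],
        }
    )
    gt.to_csv(gt_path, sep="\t", index=False)
    paths["ground_truth"] = [gt_path]
    return paths
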