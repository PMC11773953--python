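"""Validation of called miRNA-gene pairs.

Four complementary checks:

* **Held-out databases** -- what fraction of the significant pairs is
  confirmed by validation databases, after removing anything already in the
  training databases (:func:`validation_rate`).
* **Perturbation DEG overlap** -- genes differentially expressed after
  overexpressing a miRNA (two-sample t-test) intersected with predicted and
  known target sets (:func:`deg_ttest`, :func:`overlap_stats`).
* **Direction concordance** -- does the sign of the pan-cancer correlation
  agree with the regulation direction seen under perturbation
  (:func:`direction_concordance`)?  Under overexpression, up-regulated
  targets should correlate positively and down-regulated ones negatively;
  under knockdown the rule is mirrored.
* **Cross-method comparison** -- paired t-tests on per-dataset DEG-overlap
  percentages between prediction methods (:func:`paired_overlap_ttest`),
  with size-matched top-k selection (:func:`select_matched_predictions`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import pct
from .labeling import InteractionDB, union_pairs
from .simulate import PerturbationDataset

__all__ = [
    "ValidationSummary",
    "DEGResult",
    "OverlapRow",
    "ConcordanceEntry",
    "ConcordanceSummary",
    "validation_rate",
    "deg_ttest",
    "overlap_stats",
    "direction_concordance",
    "paired_overlap_ttest",
    "select_matched_predictions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationSummary:
    n_validated: int
    n_significant: int
    rate_pct: float  # percentage, 2 decimals


def validation_rate(
    significant: Iterable[tuple[str, str]],
    heldout_dbs: Sequence[InteractionDB],
    training_dbs: Sequence[InteractionDB],
) -> ValidationSummary:
    """Share of significant pairs confirmed by held-out databases only.

    A pair counts as validated iff it appears in some held-out database and
    in *no* training database; the returned rate is a percentage rounded to
    2 decimals.
    """
    significant = set(significant)
    if not significant:
        raise ValueError("significant pair set is empty")
    confirmable = union_pairs(heldout_dbs) - union_pairs(training_dbs)
    validated = significant & confirmable
    return ValidationSummary(
        n_validated=len(validated),
        n_significant=len(significant),
        rate_pct=pct(len(validated), len(significant), decimals=2),
    )


@dataclass
class DEGResult:
    """Per-gene two-sample t-test results for one perturbation experiment."""

    table: pd.DataFrame  # index: gene; columns: t, p, direction
    alpha: float = 0.05
    excluded: tuple[str, ...] = ()

    def degs(self, alpha: float | None = None) -> set[str]:
        a = self.alpha if alpha is None else alpha
        return set(self.table.index[self.table["p"] < a])

    def direction_of(self, gene: str) -> str:
        return str(self.table.at[gene, "direction"])


def deg_ttest(
    data: PerturbationDataset,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> DEGResult:
    """Gene-wise two-sample t-test, treated vs control.

    Welch's variant by default (``equal_var=True`` for pooled variance).
    Direction is the sign of the treated-minus-control mean difference.
    Genes constant in both groups have an undefined statistic and are
    excluded (logged).
    """
    control = data.control.to_numpy(dtype=float)
    treated = data.treated.to_numpy(dtype=float)
    genes = data.genes
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(treated, control, axis=0, equal_var=equal_var)
    diff = treated.mean(axis=0) - control.mean(axis=0)
    direction = np.where(diff > 0, "up", "down")
    ok = np.isfinite(t) & np.isfinite(p)
    excluded = tuple(np.asarray(genes)[~ok])
    if excluded:
        logger.info(
            "%s/%s: %d gene(s) with undefined t excluded",
            data.mirna_id, data.cohort_context, len(excluded),
        )
    table = pd.DataFrame(
        {"t": t[ok], "p": p[ok], "direction": direction[ok]},
        index=pd.Index(np.asarray(genes)[ok], name="gene"),
    )
    return DEGResult(table=table, alpha=alpha, excluded=excluded)


@dataclass(frozen=True)
class OverlapRow:
    """One perturbation dataset's overlap bookkeeping.

    Percentages are integer-rounded shares of the *source* set
    (predicted or known targets) that appear among the DEGs.
    """

    dataset_id: str
    n_degs: int
    n_predicted: int
    n_known: int
    predicted_overlap: int
    predicted_overlap_pct: int
    known_overlap: int
    known_overlap_pct: int

    def __post_init__(self) -> None:
        if self.predicted_overlap > min(self.n_predicted, self.n_degs):
            raise ValueError("predicted overlap exceeds source/DEG size")
        if self.known_overlap > min(self.n_known, self.n_degs):
            raise ValueError("known overlap exceeds source/DEG size")


def overlap_stats(
    predicted: Iterable[str],
    known: Iterable[str],
    degs: Iterable[str],
    dataset_id: str = "",
) -> OverlapRow:
    """Counts and integer percentages of predicted/known targets among DEGs."""
    predicted, known, degs = set(predicted), set(known), set(degs)
    if not predicted or not known:
        raise ValueError("predicted and known sets must be non-empty")
    p_overlap = len(predicted & degs)
    k_overlap = len(known & degs)
    return OverlapRow(
        dataset_id=dataset_id,
        n_degs=len(degs),
        n_predicted=len(predicted),
        n_known=len(known),
        predicted_overlap=p_overlap,
        predicted_overlap_pct=int(pct(p_overlap, len(predicted), decimals=0)),
        known_overlap=k_overlap,
        known_overlap_pct=int(pct(k_overlap, len(known), decimals=0)),
    )


@dataclass(frozen=True)
class ConcordanceEntry:
    """One validated pair: regulation direction vs pan-cancer correlation sign."""

    mirna: str
    gene: str
    cohort_context: str
    direction: str  # up | down (in the perturbation experiment)
    correlation_sign: str | None  # positive | negative | None (MISSING)
    perturbation: str = "overexpression"

    def is_concordant(self) -> bool | None:
        """True/False per the direction rule; None when the sign is MISSING."""
        if self.correlation_sign is None:
            return None
        expected_up = "positive" if self.perturbation == "overexpression" else "negative"
        if self.direction == "up":
            return self.correlation_sign == expected_up
        return self.correlation_sign != expected_up


@dataclass(frozen=True)
class ConcordanceSummary:
    concordant: int
    total: int
    percentage: int  # nearest integer
    n_skipped: int = 0


def direction_concordance(entries: Sequence[ConcordanceEntry]) -> ConcordanceSummary:
    """Count entries whose correlation sign matches the regulation direction.

    Entries with a MISSING correlation sign are skipped (logged), not
    imputed.
    """
    if not entries:
        raise ValueError("no concordance entries")
    verdicts = [e.is_concordant() for e in entries]
    skipped = sum(v is None for v in verdicts)
    if skipped:
        logger.info("%d entr(ies) skipped for missing correlation sign", skipped)
    usable = [v for v in verdicts if v is not None]
    if not usable:
        raise ValueError("all entries lack a correlation sign")
    concordant = sum(usable)
    return ConcordanceSummary(
        concordant=concordant,
        total=len(usable),
        percentage=int(pct(concordant, len(usable), decimals=0)),
        n_skipped=skipped,
    )


def paired_overlap_ttest(
    percent_a: Sequence[float], percent_b: Sequence[float]
) -> tuple[float, float]:
    """Paired two-sided t-test on element-wise overlap-percentage differences.

    Identical vectors return (0.0, 1.0) -- there is no evidence of any
    difference -- rather than the undefined 0/0 statistic.
    """
    a = np.asarray(percent_a, dtype=float)
    b = np.asarray(percent_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.all(a == b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def pairwise_overlap_matrix(
    percent_by_method: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Symmetric matrix of paired t-test p-values between methods (NaN diagonal)."""
    methods = list(percent_by_method)
    out = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for mj in methods[i + 1:]:
            _, p = paired_overlap_ttest(percent_by_method[mi], percent_by_method[mj])
            out.at[mi, mj] = out.at[mj, mi] = p
    return out


def select_matched_predictions(
    scores: Mapping[str, float] | pd.Series, k: int
) -> set[str]:
    """Top-``k`` genes by score; ties broken by lexicographic gene id.

    Used to size-match an external tool's prediction list to ours before
    comparing DEG overlap.
    """
    items = list(scores.items())
    if k > len(items):
        raise ValueError(f"k={k} exceeds the {len(items)} scored genes")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return {gene for gene, _ in items[:k]}
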