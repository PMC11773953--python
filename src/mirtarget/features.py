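"""Per-cohort miRNA-gene correlation features.

Each candidate miRNA-gene pair is described by a vector of per-cohort
Pearson correlations.  Within a cohort the correlation is computed only over
the samples that express *both* the miRNA and the gene (value > 0), and only
when the number of such co-expressing samples strictly exceeds
``min_coexpressing`` (default 10); otherwise the cell is MISSING.  Pairs
whose correlation is MISSING in more than ``max_missing`` cohorts (default
3) are excluded from the feature table altogether.

MISSING is carried as NaN so that gradient-boosted trees can consume the
table natively; ``FeatureTable.imputed(0.0)`` offers a zero-fill fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import UndefinedCorrelationError
from .simulate import ExpressionPanel

__all__ = [
    "MISSING",
    "PairKey",
    "FeatureTable",
    "pearson_r",
    "coexpressing_samples",
    "cohort_correlation",
    "build_feature_table",
]

MISSING = np.nan

_VAR_EPS = 1e-12


class PairKey(NamedTuple):
    mirna: str
    gene: str


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` for vectors shorter than 2 or
    with zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise UndefinedCorrelationError(f"need >= 2 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx <= _VAR_EPS * max(1.0, float(x @ x)) or vy <= _VAR_EPS * max(1.0, float(y @ y)):
        raise UndefinedCorrelationError("constant input vector")
    r = float(dx @ dy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def coexpressing_samples(mi: Sequence[float], g: Sequence[float]) -> np.ndarray:
    """Indices of samples where both the miRNA and the gene are expressed (> 0)."""
    mi = np.asarray(mi, dtype=float)
    g = np.asarray(g, dtype=float)
    if mi.shape != g.shape:
        raise ValueError("vectors must have equal length")
    return np.flatnonzero((mi > 0) & (g > 0))


def cohort_correlation(
    panel: ExpressionPanel,
    pair: PairKey | tuple[str, str],
    min_coexpressing: int = 10,
    subset_only: bool = True,
) -> float:
    """Correlation of one pair in one cohort, or MISSING (NaN).

    The cell is MISSING unless the co-expressing sample count *strictly
    exceeds* ``min_coexpressing``, or when the usable sub-vectors are
    constant.  With ``subset_only=False`` the co-expression count still
    gates the cell but the correlation itself uses all samples.
    """
    mirna_id, gene_id = pair
    try:
        mi = panel.mirna[mirna_id].to_numpy(dtype=float)
        g = panel.genes[gene_id].to_numpy(dtype=float)
    except KeyError as exc:
        raise KeyError(f"unknown feature {exc} in cohort {panel.cohort_id}") from exc
    idx = coexpressing_samples(mi, g)
    if idx.size <= min_coexpressing:
        return MISSING
    if subset_only:
        mi, g = mi[idx], g[idx]
    try:
        return pearson_r(mi, g)
    except UndefinedCorrelationError:
        return MISSING


def _masked_pearson_matrix(
    X: np.ndarray, Y: np.ndarray, min_coexpressing: int
) -> np.ndarray:
    """All-pairs Pearson r over co-expressing samples only, NaN where undefined.

    Entries are exactly 0 when not expressed, so the masked sums reduce to
    plain matrix products between the raw matrices and the 0/1 support
    indicators; no per-pair loop is needed.
    """
    Xp = (X > 0).astype(float)
    Yp = (Y > 0).astype(float)
    n = Xp.T @ Yp
    sx = X.T @ Yp
    sy = Xp.T @ Y
    sxx = (X * X).T @ Yp
    syy = Xp.T @ (Y * Y)
    sxy = X.T @ Y
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    bad = (
        (n <= min_coexpressing)
        | (vx <= _VAR_EPS * np.maximum(1.0, sxx))
        | (vy <= _VAR_EPS * np.maximum(1.0, syy))
    )
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0)


def _plain_pearson_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Pearson r over all samples (no masking)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    vx = (Xc * Xc).sum(axis=0)
    vy = (Yc * Yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Yc) / np.sqrt(np.outer(vx, vy))
    bad = np.outer(vx <= _VAR_EPS * np.maximum(1.0, (X * X).sum(axis=0)),
                   np.ones(Y.shape[1], dtype=bool))
    bad |= np.outer(np.ones(X.shape[1], dtype=bool),
                    vy <= _VAR_EPS * np.maximum(1.0, (Y * Y).sum(axis=0)))
    r[bad | (np.ones_like(r, dtype=bool) if n < 2 else np.zeros_like(r, dtype=bool))] = np.nan
    return np.clip(r, -1.0, 1.0)


@dataclass
class FeatureTable:
    """pair x cohort correlation matrix with per-pair missingness metadata.

    ``values`` is indexed by a (mirna, gene) MultiIndex; columns are cohort
    ids; MISSING cells are NaN.  ``n_dropped`` counts pairs excluded by the
    missing-cohort rule.
    """

    values: pd.DataFrame
    n_missing: pd.Series
    n_dropped: int = 0
    max_missing: int = 3

    @property
    def pairs(self) -> list[PairKey]:
        return [PairKey(*t) for t in self.values.index]

    @property
    def cohorts(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    @property
    def n_unique_mirnas(self) -> int:
        return self.values.index.get_level_values(0).nunique()

    @property
    def n_unique_genes(self) -> int:
        return self.values.index.get_level_values(1).nunique()

    def imputed(self, fill: float = 0.0) -> pd.DataFrame:
        return self.values.fillna(fill)

    def correlation_sign(self, mirna: str, gene: str, cohort: str) -> str | None:
        """'positive'/'negative' sign of one cell, or None when MISSING/zero."""
        try:
            value = self.values.at[(mirna, gene), cohort]
        except KeyError:
            return None
        if pd.isna(value) or value == 0:
            return None
        return "positive" if value > 0 else "negative"


def build_feature_table(
    panels: Sequence[ExpressionPanel],
    max_missing: int = 3,
    min_coexpressing: int = 10,
    subset_only: bool = True,
) -> FeatureTable:
    """Evaluate every miRNA x gene pair across all cohorts.

    Pairs MISSING in more than ``max_missing`` cohorts are dropped.
    """
    if not panels:
        raise ValueError("need at least one panel")
    mirnas = list(panels[0].mirna.columns)
    genes = list(panels[0].genes.columns)
    for p in panels[1:]:
        if list(p.mirna.columns) != mirnas or list(p.genes.columns) != genes:
            raise ValueError(f"panel {p.cohort_id}: inconsistent feature universe")

    columns = {}
    for p in panels:
        X = p.mirna.to_numpy(dtype=float)
        Y = p.genes.to_numpy(dtype=float)
        if subset_only:
            r = _masked_pearson_matrix(X, Y, min_coexpressing)
        else:
            n = (X > 0).astype(float).T @ (Y > 0).astype(float)
            r = _plain_pearson_matrix(X, Y)
            r[n <= min_coexpressing] = np.nan
        columns[p.cohort_id] = r.ravel()

    index = pd.MultiIndex.from_product([mirnas, genes], names=["mirna", "gene"])
    values = pd.DataFrame(columns, index=index)
    n_missing = values.isna().sum(axis=1)
    keep = n_missing <= max_missing
    return FeatureTable(
        values=values.loc[keep],
        n_missing=n_missing.loc[keep],
        n_dropped=int((~keep).sum()),
        max_missing=max_missing,
    )
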