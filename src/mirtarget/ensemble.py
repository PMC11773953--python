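"""Repeated-downsampling gradient-boosted ensemble and consensus calling.

The positive class (database-confirmed pairs) is a tiny fraction of the
pair universe, so a single classifier trained on all pairs would collapse
to the negative class.  Instead, for each downsampling rate the negative
class is subsampled ``n_models`` times; each subsample plus the full
positive class is split 80/20 (stratified), an XGBoost classifier is fitted
on the training part and evaluated on the test part, and the fitted model
then scores *every* negative-labelled pair.  A pair's consensus count is
the number of models scoring it at or above ``positive_threshold``; pairs
reaching a frequency threshold are called significant, i.e. proposed as
undiscovered miRNA-target interactions.

Correlation features may contain NaN (MISSING cohorts); XGBoost consumes
them natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from ._util import DegenerateTrainingError
from .features import FeatureTable
from .labeling import LabelSet

FeatureTableLike = FeatureTable | pd.DataFrame

__all__ = [
    "EnsembleConfig",
    "ModelRunMetrics",
    "ConsensusResult",
    "downsample_negatives",
    "train_one",
    "run_suite",
    "call_significant",
    "metric_summary",
]

logger = logging.getLogger(__name__)

# The reference grid uses frequency thresholds {700, 800, 900, 950} out of
# 1000 models; expressed as fractions they rescale to any suite size.
FREQ_FRACTIONS = (0.70, 0.80, 0.90, 0.95)


@dataclass(frozen=True)
class EnsembleConfig:
    """Suite layout: downsampling grid, models per rate, calling thresholds."""

    downsample_rates: tuple[float, ...] = (0.01, 0.05, 0.10, 0.5, 1.0)
    n_models: int = 50
    train_fraction: float = 0.8
    positive_threshold: float = 0.5
    freq_thresholds: tuple[int, ...] | None = None
    base_seed: int = 0
    learner_params: Mapping[str, object] = field(default_factory=dict)
    exclude_train: bool = False

    def __post_init__(self) -> None:
        if not self.downsample_rates:
            raise ValueError("need at least one downsample rate")
        for rate in self.downsample_rates:
            if not 0 < rate <= 1:
                raise ValueError(f"downsample rate must be in (0, 1], got {rate}")
        if self.n_models <= 0:
            raise ValueError("n_models must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        for t in self.resolved_freq_thresholds:
            if not 0 <= t <= self.n_models:
                raise ValueError(
                    f"frequency threshold {t} outside 0..n_models={self.n_models}"
                )

    @property
    def resolved_freq_thresholds(self) -> tuple[int, ...]:
        if self.freq_thresholds is not None:
            return tuple(self.freq_thresholds)
        return tuple(int(round(f * self.n_models)) for f in FREQ_FRACTIONS)


@dataclass(frozen=True)
class ModelRunMetrics:
    """Test-split accuracy of one model, reported per class."""

    recall_positive: float
    specificity_negative: float  # 1 - false positive rate
    auc: float

    def __post_init__(self) -> None:
        for name in ("recall_positive", "specificity_negative", "auc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def downsample_negatives(labels: LabelSet, rate: float, seed: int) -> np.ndarray:
    """Uniform without-replacement sample of ``round(rate * n_negative)``
    negative positions (into ``labels.labels``); deterministic in ``seed``."""
    if not 0 < rate <= 1:
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    neg_positions = np.flatnonzero(~labels.labels.to_numpy())
    k = int(round(rate * neg_positions.size))
    if k < 1:
        raise ValueError(
            f"rate {rate} yields an empty negative subsample "
            f"(n_negative={neg_positions.size})"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(neg_positions, size=k, replace=False))


def _make_learner(seed: int, learner_params: Mapping[str, object]) -> XGBClassifier:
    params: dict[str, object] = {
        "n_jobs": 1,
        "random_state": seed,
        "tree_method": "hist",
    }
    params.update(learner_params)
    return XGBClassifier(**params)


def train_one(
    features: np.ndarray | pd.DataFrame,
    labels_subset: np.ndarray | pd.Series,
    split_seed: int,
    learner_params: Mapping[str, object] | None = None,
    train_fraction: float = 0.8,
    positive_threshold: float = 0.5,
) -> tuple[XGBClassifier, ModelRunMetrics]:
    """Fit one classifier on a (positives + downsampled negatives) subset.

    The subset is split 80/20 stratified by class; metrics are computed on
    the held-out 20%.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels_subset, dtype=bool)
    if y.all() or not y.any():
        raise DegenerateTrainingError("training subset contains a single class")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y,
        train_size=train_fraction,
        random_state=split_seed,
        stratify=y,
    )
    model = _make_learner(split_seed, learner_params or {})
    model.fit(X_train, y_train.astype(int))
    scores = model.predict_proba(X_test)[:, 1]
    calls = scores >= positive_threshold
    pos, neg = y_test, ~y_test
    recall = float(calls[pos].mean()) if pos.any() else float("nan")
    specificity = float((~calls[neg]).mean()) if neg.any() else float("nan")
    auc = float(roc_auc_score(y_test, scores))
    return model, ModelRunMetrics(recall, specificity, auc)


@dataclass
class ConsensusResult:
    """Per-negative-pair positive-call counts for each downsampling rate."""

    n_models: int
    pair_index: pd.MultiIndex  # the negative-labelled pairs, in label order
    counts: dict[float, np.ndarray]
    metrics: dict[float, list[ModelRunMetrics]]
    freq_thresholds: tuple[int, ...]

    def counts_series(self, rate: float) -> pd.Series:
        return pd.Series(self._counts_for(rate), index=self.pair_index, name="count")

    def _counts_for(self, rate: float) -> np.ndarray:
        try:
            return self.counts[rate]
        except KeyError:
            raise KeyError(
                f"unknown rate {rate}; available: {sorted(self.counts)}"
            ) from None

    def significant(self, rate: float, freq_threshold: int) -> set[tuple[str, str]]:
        if freq_threshold > self.n_models:
            raise ValueError(
                f"freq_threshold {freq_threshold} exceeds n_models {self.n_models}"
            )
        counts = self._counts_for(rate)
        return set(self.pair_index[counts >= freq_threshold])

    def grid(self) -> pd.DataFrame:
        """Significant-pair counts over the rate x frequency-threshold grid."""
        rows = {
            rate: {t: len(self.significant(rate, t)) for t in self.freq_thresholds}
            for rate in self.counts
        }
        out = pd.DataFrame(rows).T
        out.index.name = "rate"
        out.columns.name = "freq_threshold"
        return out


def call_significant(
    result: ConsensusResult, rate: float, freq_threshold: int
) -> set[tuple[str, str]]:
    """Pairs called positive by at least ``freq_threshold`` of the models."""
    return result.significant(rate, freq_threshold)


def run_suite(
    features: "FeatureTable | pd.DataFrame",
    labels: LabelSet,
    config: EnsembleConfig,
) -> ConsensusResult:
    """Train the full rate grid and accumulate consensus counts.

    ``features`` may be a :class:`~mirtarget.features.FeatureTable` or a
    DataFrame aligned with ``labels.labels``.  Each model's seed is derived
    from ``base_seed`` plus its position in the grid, so results do not
    depend on training order.
    """
    if isinstance(features, FeatureTable):
        X_df = features.values
    elif isinstance(features, pd.DataFrame):
        X_df = features
    else:
        raise TypeError("features must be a FeatureTable or pairs x cohorts DataFrame")
    if not X_df.index.equals(labels.labels.index):
        raise ValueError("features and labels are not aligned")
    X = X_df.to_numpy(dtype=float)
    y = labels.labels.to_numpy()
    pos_positions = np.flatnonzero(y)
    neg_positions = np.flatnonzero(~y)
    if pos_positions.size == 0 or neg_positions.size == 0:
        raise DegenerateTrainingError("need both classes to train the suite")
    X_neg = X[neg_positions]
    neg_rank = {p: i for i, p in enumerate(neg_positions)}

    counts: dict[float, np.ndarray] = {}
    metrics: dict[float, list[ModelRunMetrics]] = {}
    for rate_idx, rate in enumerate(config.downsample_rates):
        rate_counts = np.zeros(neg_positions.size, dtype=int)
        rate_metrics: list[ModelRunMetrics] = []
        for i in range(config.n_models):
            seed = config.base_seed + rate_idx * config.n_models + i
            sub = downsample_negatives(labels, rate, seed)
            train_positions = np.concatenate([pos_positions, sub])
            model, m = train_one(
                X[train_positions],
                y[train_positions],
                split_seed=seed,
                learner_params=config.learner_params,
                train_fraction=config.train_fraction,
                positive_threshold=config.positive_threshold,
            )
            scores = model.predict_proba(X_neg)[:, 1]
            calls = scores >= config.positive_threshold
            if config.exclude_train:
                calls[[neg_rank[p] for p in sub]] = False
            rate_counts += calls
            rate_metrics.append(m)
        counts[rate] = rate_counts
        metrics[rate] = rate_metrics
        logger.info(
            "rate %.3g: mean recall %.3f, mean specificity %.3f",
            rate,
            float(np.mean([m.recall_positive for m in rate_metrics])),
            float(np.mean([m.specificity_negative for m in rate_metrics])),
        )

    return ConsensusResult(
        n_models=config.n_models,
        pair_index=labels.labels.index[~y],
        counts=counts,
        metrics=metrics,
        freq_thresholds=config.resolved_freq_thresholds,
    )


def metric_summary(result: ConsensusResult) -> pd.DataFrame:
    """Mean per-model test metrics for each downsampling rate."""
    rows = []
    for rate, ms in result.metrics.items():
        rows.append(
            {
                "rate": rate,
                "mean_recall": float(np.mean([m.recall_positive for m in ms])),
                "mean_specificity": float(np.mean([m.specificity_negative for m in ms])),
                "mean_auc": float(np.mean([m.auc for m in ms])),
            }
        )
    return pd.DataFrame(rows).set_index("rate")

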