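"""Interaction databases, identifier canonicalization, and binary labels.

Curated miRNA-target databases play two distinct roles: *training*
databases define the positive class, while *validation* databases are held
out strictly for evaluating predictions.  A pair retained in the feature
table is labelled positive iff it appears in the union of the training
databases; everything else is negative.  Because database coverage is
sparse, the negative class mixes truly unrelated pairs with real but
unreported interactions -- which is exactly what the consensus ensemble
mines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import MirtargetError, pct
from .features import FeatureTable

__all__ = [
    "InteractionDB",
    "LabelSet",
    "LeakageError",
    "load_interaction_db",
    "normalize_mirna_id",
    "normalize_gene_symbol",
    "assign_labels",
]

logger = logging.getLogger(__name__)

ROLES = ("training", "validation")


class LeakageError(MirtargetError):
    """A validation-role database was offered for label construction."""


def normalize_mirna_id(raw: str, strip_arm: bool = False) -> str:
    """Canonical miRNA name: lowercase, species prefix removed.

    ``hsa-miR-335-5p`` -> ``mir-335-5p`` (or ``mir-335`` with
    ``strip_arm=True``); ``hsa-let-7b`` -> ``let-7b``.  Idempotent.
    """
    name = raw.strip().lower()
    if not name:
        raise ValueError("empty miRNA id")
    while name.startswith("hsa-"):
        name = name[len("hsa-"):]
    while strip_arm and (name.endswith("-5p") or name.endswith("-3p")):
        name = name[:-3]
    if not name:
        raise ValueError(f"miRNA id {raw!r} is empty after canonicalization")
    return name


def normalize_gene_symbol(raw: str) -> str:
    """Canonical gene symbol: uppercase, surrounding whitespace stripped."""
    symbol = raw.strip().upper()
    if not symbol:
        raise ValueError("empty gene symbol")
    return symbol


@dataclass(frozen=True)
class InteractionDB:
    """A named set of canonical (miRNA, gene) pairs with a fixed role."""

    name: str
    role: str  # training | validation
    pairs: frozenset[tuple[str, str]]
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def load_interaction_db(
    path: str,
    name: str,
    role: str,
    header: bool = True,
    strip_arm: bool = False,
) -> InteractionDB:
    """Read a two-column (miRNA, gene) TSV into a canonical, de-duplicated DB."""
    rows = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if rows.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (miRNA, gene)")
    pairs: list[tuple[str, str]] = []
    for i, (raw_m, raw_g) in enumerate(rows.iloc[:, :2].itertuples(index=False)):
        line = i + (2 if header else 1)
        if pd.isna(raw_m) or pd.isna(raw_g):
            raise ValueError(f"{path}: malformed row at line {line}")
        try:
            pairs.append(
                (normalize_mirna_id(raw_m, strip_arm=strip_arm),
                 normalize_gene_symbol(raw_g))
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {line}: {exc}") from exc
    unique = frozenset(pairs)
    n_dup = len(pairs) - len(unique)
    if n_dup:
        logger.info("%s: %d duplicate pair(s) collapsed", name, n_dup)
    return InteractionDB(name=name, role=role, pairs=unique, n_duplicates=n_dup)


@dataclass
class LabelSet:
    """Binary labels aligned to the retained feature-table pairs."""

    labels: pd.Series  # bool, indexed by the (mirna, gene) MultiIndex
    n_unmatched_db_pairs: int = 0

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    @property
    def n_pairs(self) -> int:
        return len(self.labels)

    @property
    def positive_fraction_pct(self) -> float:
        """Positive share of all retained pairs, in %, 2 decimals."""
        return pct(self.n_positive, self.n_pairs, decimals=2)

    def positive_pairs(self) -> set[tuple[str, str]]:
        return set(self.labels.index[self.labels])

    def negative_pairs(self) -> set[tuple[str, str]]:
        return set(self.labels.index[~self.labels])


def union_pairs(dbs: Iterable[InteractionDB]) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for db in dbs:
        out |= db.pairs
    return out


def assign_labels(table: FeatureTable, training_dbs: Sequence[InteractionDB]) -> LabelSet:
    """Label every retained pair positive iff it is in a training database.

    Refuses validation-role databases (leakage guard).  Database pairs that
    failed feature-table eligibility are dropped from the positive class and
    counted in ``n_unmatched_db_pairs``.
    """
    for db in training_dbs:
        if db.role != "training":
            raise LeakageError(
                f"database {db.name!r} has role {db.role!r}; only training "
                "databases may define labels"
            )
    known = union_pairs(training_dbs)
    labels = pd.Series(table.values.index.isin(known), index=table.values.index)
    n_unmatched = len(known) - int(labels.sum())
    if n_unmatched:
        logger.info(
            "%d training-database pair(s) absent from the feature table", n_unmatched
        )
    return LabelSet(labels=labels, n_unmatched_db_pairs=n_unmatched)
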