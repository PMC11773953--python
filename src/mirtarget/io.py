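"""TSV readers and writers for every pipeline artifact.

One interchange dialect throughout: tab-delimited UTF-8, header row,
sample/pair identifiers in the leading column(s), missing values written as
``NA``.  Readers validate shape and numeric content and report the first
offending cell by row and column (1-based file coordinates, header
included).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable
from .labeling import LabelSet
from .simulate import ExpressionPanel, PerturbationDataset

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_panel",
    "read_panels_dir",
    "write_interaction_tsv",
    "write_feature_table",
    "read_feature_table",
    "write_labels",
    "read_labels",
    "write_consensus_counts",
    "write_perturbation_tsv",
    "read_perturbation_tsv",
]

NA = "NA"


def _parse_numeric_block(raw: pd.DataFrame, path: str, allow_na: bool = False,
                         allow_negative: bool = False,
                         col_offset: int = 2) -> pd.DataFrame:
    """Convert a string-typed frame to floats, naming the first bad cell.

    Row/column numbers are 1-based file coordinates: row 1 is the header,
    column 1 the identifier column.
    """
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty data section")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().to_numpy()
    if allow_na:
        bad &= ~(raw == NA).to_numpy() & ~raw.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {r + 2}, column {c + col_offset} "
            f"(value {raw.iat[r, c]!r})"
        )
    if not allow_negative:
        neg = (values.to_numpy() < 0)
        neg &= ~np.isnan(values.to_numpy())
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"{path}: negative value at row {r + 2}, column {c + col_offset}"
            )
    if not allow_na and not np.isfinite(values.to_numpy()).all():
        raise ValueError(f"{path}: non-finite values present")
    return values


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a samples x features expression matrix.

    First column holds sample ids, header row holds feature ids; all values
    must be finite and non-negative.
    """
    path = os.fspath(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed TSV ({exc})") from exc
    values = _parse_numeric_block(raw, path)
    values.index.name = None  # the id header is presentation, not data
    return values


def write_expression_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(os.fspath(path), sep="\t", index_label="sample")


def read_panel(cohort_id: str, mirna_path: str, genes_path: str) -> ExpressionPanel:
    return ExpressionPanel(
        cohort_id=cohort_id,
        mirna=read_expression_tsv(mirna_path),
        genes=read_expression_tsv(genes_path),
    )


def read_panels_dir(panel_dir: str | os.PathLike) -> list[ExpressionPanel]:
    """Read every ``<cohort>_mirna.tsv`` / ``<cohort>_genes.tsv`` pair in a
    directory (the :func:`mirtarget.simulate.write_fixtures` layout)."""
    panel_dir = os.fspath(panel_dir)
    cohorts = sorted(
        f[: -len("_mirna.tsv")]
        for f in os.listdir(panel_dir)
        if f.endswith("_mirna.tsv")
    )
    if not cohorts:
        raise ValueError(f"{panel_dir}: no '<cohort>_mirna.tsv' files found")
    return [
        read_panel(
            c,
            os.path.join(panel_dir, f"{c}_mirna.tsv"),
            os.path.join(panel_dir, f"{c}_genes.tsv"),
        )
        for c in cohorts
    ]


def write_interaction_tsv(
    pairs: Iterable[tuple[str, str]], path: str | os.PathLike
) -> None:
    df = pd.DataFrame(sorted(pairs), columns=["mirna", "gene"])
    df.to_csv(os.fspath(path), sep="\t", index=False)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    table.values.to_csv(os.fspath(path), sep="\t", na_rep=NA)


def read_feature_table(path: str | os.PathLike, max_missing: int = 3) -> FeatureTable:
    path = os.fspath(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected mirna, gene and >=1 cohort column")
    index = pd.MultiIndex.from_frame(raw.iloc[:, :2].set_axis(["mirna", "gene"], axis=1))
    values = _parse_numeric_block(
        raw.iloc[:, 2:], path, allow_na=True, allow_negative=True, col_offset=3
    )
    values.index = index
    return FeatureTable(
        values=values,
        n_missing=values.isna().sum(axis=1),
        n_dropped=0,
        max_missing=max_missing,
    )


def write_labels(labels: LabelSet, path: str | os.PathLike) -> None:
    out = labels.labels.map({True: "positive", False: "negative"}).rename("label")
    out.to_frame().to_csv(os.fspath(path), sep="\t")


def read_labels(path: str | os.PathLike) -> LabelSet:
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"mirna", "gene", "label"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    bad = ~df["label"].isin(["positive", "negative"])
    if bad.any():
        raise ValueError(f"{path}: unknown label at line {int(np.flatnonzero(bad)[0]) + 2}")
    labels = pd.Series(
        (df["label"] == "positive").to_numpy(),
        index=pd.MultiIndex.from_frame(df[["mirna", "gene"]]),
    )
    return LabelSet(labels=labels)


def write_consensus_counts(result, path: str | os.PathLike) -> None:
    """Long-format consensus output: mirna, gene, rate, count."""
    frames = []
    for rate in result.counts:
        s = result.counts_series(rate).reset_index()
        s.insert(2, "rate", rate)
        frames.append(s)
    pd.concat(frames, ignore_index=True).to_csv(os.fspath(path), sep="\t", index=False)


def write_perturbation_tsv(ds: PerturbationDataset, path: str | os.PathLike) -> None:
    """Write a two-group experiment with a ``group`` label column."""
    both = pd.concat(
        [
            ds.control.assign(group="control"),
            ds.treated.assign(group="treated"),
        ]
    )
    cols = ["group"] + ds.genes
    both[cols].to_csv(os.fspath(path), sep="\t", index_label="sample")


def read_perturbation_tsv(
    path: str | os.PathLike,
    mirna_id: str,
    cohort_context: str,
    perturbation: str = "overexpression",
) -> PerturbationDataset:
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    groups = df.pop("group")
    unknown = set(groups) - {"control", "treated"}
    if unknown:
        raise ValueError(f"{path}: unknown group label(s) {sorted(unknown)}")
    values = _parse_numeric_block(df, path)
    values.index.name = None
    return PerturbationDataset(
        mirna_id=mirna_id,
        cohort_context=cohort_context,
        control=values.loc[groups == "control"],
        treated=values.loc[groups == "treated"],
        perturbation=perturbation,
    )
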