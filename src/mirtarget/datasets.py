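"""Small bundled datasets.

``published_concordance_entries`` loads a compiled table of published
miRNA-overexpression experiments (five human miRNAs across nine GEO
series): for each gene that responded to the perturbation, the observed
regulation direction and the sign of the miRNA-gene expression correlation
in the matched TCGA cancer type.  It serves as a worked real-data input for
:func:`mirtarget.validation.direction_concordance`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validation import ConcordanceEntry

__all__ = ["published_concordance_entries", "published_concordance_table"]


def published_concordance_table() -> pd.DataFrame:
    """The raw bundled table (mirna, dataset, cohort_context, direction,
    correlation_sign, gene)."""
    ref = resources.files("mirtarget.data").joinpath("published_concordance.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def published_concordance_entries() -> list[ConcordanceEntry]:
    """The bundled table as :class:`ConcordanceEntry` objects (all
    overexpression experiments)."""
    df = published_concordance_table()
    return [
        ConcordanceEntry(
            mirna=row.mirna,
            gene=row.gene,
            cohort_context=row.cohort_context,
            direction=row.direction,
            correlation_sign=row.correlation_sign,
            perturbation="overexpression",
        )
        for row in df.itertuples(index=False)
    ]
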