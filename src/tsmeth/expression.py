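"""TPM expression matrix loading, filtering, transformation and sample QC.

The matrix is genes x samples (TPM, non-negative). A sample sheet maps each
sample to a tissue and a sequencing batch. Filtering follows the two
conventions used for tissue-specificity work: keep genes detected (TPM > 0)
in at least one sample, or keep genes reaching TPM >= 1 in at least one
sample before computing specificity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import IO

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleCorrelationSummary",
    "load_expression",
    "filter_expressed",
    "log_transform",
    "pairwise_sample_correlation",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus the sample -> tissue/batch sheet."""

    values: pd.DataFrame          # genes x samples
    sample_sheet: pd.DataFrame    # indexed by sample; columns: tissue, batch

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_sheet.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        # keep only sheet rows that correspond to matrix columns, matrix order
        self.sample_sheet = self.sample_sheet.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> pd.Series:
        """sample -> tissue, in matrix column order."""
        return self.sample_sheet["tissue"]

    @property
    def tissue_order(self) -> list[str]:
        """Tissue labels in order of first appearance in the sheet."""
        seen: dict[str, None] = {}
        for t in self.tissues:
            seen.setdefault(t, None)
        return list(seen)


@dataclass
class SampleCorrelationSummary:
    matrix: pd.DataFrame        # sample x sample Pearson r
    mean_within_tissue: float
    mean_between_tissue: float
    n_within_pairs: int
    n_between_pairs: int


def load_expression(matrix_stream: IO[str] | str, sheet_stream: IO[str] | str) -> ExpressionMatrix:
    """Read a genes-x-samples TPM TSV and a sample sheet TSV.

    The matrix header row holds sample ids and the first column gene ids;
    the sheet has columns ``sample``, ``tissue``, ``batch``. Every matrix
    sample must appear in the sheet; extra sheet rows are dropped.
    """
    values = pd.read_csv(matrix_stream, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id rows: {dups}")
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(d) for d in values.dtypes]
    ].tolist()
    if non_numeric:
        # locate the first bad cell for the diagnostic
        for col in non_numeric:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & values[col].notna()
            if bad.any():
                gene = values.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {gene!r}, sample {col!r}"
                )
        raise ValueError(f"non-numeric columns: {non_numeric}")
    if (values.to_numpy() < 0).any():
        raise ValueError("negative TPM values in expression matrix")

    sheet = pd.read_csv(sheet_stream, sep="\t", dtype=str)
    required = {"sample", "tissue", "batch"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("sample")
    if sheet.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample sheet")
    return ExpressionMatrix(values.astype(float), sheet)


def filter_expressed(matrix: ExpressionMatrix, mode: str = "any_positive") -> ExpressionMatrix:
    """Drop undetected genes.

    ``any_positive`` keeps genes with max TPM > 0 (detected anywhere);
    ``max_ge_one`` keeps genes with max TPM >= 1 (the pre-filter for the
    Tau specificity score). Gene order is preserved; idempotent.
    """
    row_max = matrix.values.max(axis=1)
    if mode == "any_positive":
        keep = row_max > 0
    elif mode == "max_ge_one":
        keep = row_max >= 1
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.sample_sheet.copy())


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); zeros map to 0 and the transform is monotone."""
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), matrix.sample_sheet.copy())


def pairwise_sample_correlation(matrix: ExpressionMatrix) -> SampleCorrelationSummary:
    """All-pairs Pearson correlation between samples, summarised by tissue.

    Within-/between-tissue means are taken over unordered off-diagonal
    pairs. A sample with zero variance across genes has undefined
    correlations; its pairs are excluded from the means with a warning.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples for pairwise correlation")
    corr = matrix.values.corr(method="pearson")  # sample x sample; NaN for zero variance
    degenerate = matrix.values.std(axis=0, ddof=0) == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance samples excluded from correlation means: "
            f"{list(matrix.values.columns[degenerate])}",
            stacklevel=2,
        )

    tissues = matrix.tissues
    within, between = [], []
    for a, b in combinations(matrix.samples, 2):
        r = corr.loc[a, b]
        if np.isnan(r):
            continue
        (within if tissues[a] == tissues[b] else between).append(r)
    return SampleCorrelationSummary(
        matrix=corr,
        mean_within_tissue=float(np.mean(within)) if within else float("nan"),
        mean_between_tissue=float(np.mean(between)) if between else float("nan"),
        n_within_pairs=len(within),
        n_between_pairs=len(between),
    )
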