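"""Count-matrix normalization and abundance filtering.

The mRNA path follows the median-of-ratios convention: per-sample size
factors are the median, over genes with all-positive counts, of the count
divided by the gene's geometric mean across samples; normalized counts are
then length-normalized to FPKM and log-transformed as log2(1 + FPKM). The
miRNA path is identical except that length normalization is replaced by
reads-per-million (RPM).

Each matrix carries an explicit ``scale`` tag and transitions are only
allowed through the defined operations, so accidentally normalizing twice
or filtering on the wrong scale is a hard error rather than a silent bug.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionError",
    "ExpressionMatrix",
    "FilterReport",
    "SCALES",
    "size_factors",
    "normalize_counts",
    "to_fpkm",
    "to_rpm",
    "log2p1",
    "cumulative_abundance_filter",
    "expressed_above",
    "read_counts_tsv",
    "read_gene_lengths",
    "read_sample_sheet",
    "select_samples",
]

SCALES = ("raw_counts", "size_normalized", "fpkm", "rpm", "log2p1")
_LINEAR_SCALES = ("raw_counts", "size_normalized", "fpkm", "rpm")


class ExpressionError(ValueError):
    """Invalid matrix content or a disallowed scale transition."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples matrix with an explicit scale tag.

    ``gene_lengths`` (bp per row) must be attached before FPKM conversion
    and must be absent on the miRNA RPM path.
    """

    values: pd.DataFrame
    scale: str = "raw_counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ExpressionError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        arr = self.values.to_numpy()
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ExpressionError("expression values must be finite and non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ExpressionError("duplicate row or sample ids")
        if self.gene_lengths is not None:
            missing = self.values.index.difference(self.gene_lengths.index)
            if len(missing):
                raise ExpressionError(
                    f"gene lengths missing for {len(missing)} rows, e.g. {list(missing[:3])}"
                )
            if (self.gene_lengths.reindex(self.values.index) <= 0).any():
                raise ExpressionError("gene lengths must be positive")

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def _require(self, scale: str, op: str) -> None:
        if self.scale != scale:
            raise ExpressionError(f"{op} requires scale {scale!r}, matrix is {self.scale!r}")


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are rows with strictly positive counts in every sample;
    s_j = median_i counts[i, j] / geomean_i(counts[i, :]).
    """
    matrix._require("raw_counts", "size_factors")
    counts = matrix.values
    reference = counts[(counts > 0).all(axis=1)]
    if reference.empty:
        raise ExpressionError(
            "no gene has all-positive counts across samples; pre-filter empty rows "
            "or low-coverage samples before computing size factors"
        )
    log_geomean = np.log(reference).mean(axis=1)
    ratios = np.exp(np.log(reference).sub(log_geomean, axis=0))
    factors = ratios.median(axis=0)
    factors.name = "size_factor"
    return factors


def normalize_counts(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample by its size factor (raw -> size_normalized)."""
    matrix._require("raw_counts", "normalize_counts")
    if not matrix.sample_ids.equals(factors.index.astype(matrix.sample_ids.dtype)):
        missing = matrix.sample_ids.difference(factors.index)
        if len(missing):
            raise ExpressionError(f"size factors missing for samples {list(missing[:5])}")
        factors = factors.reindex(matrix.sample_ids)
    if (factors <= 0).any() or factors.isna().any():
        raise ExpressionError("size factors must be positive")
    return replace(matrix, values=matrix.values.div(factors, axis=1), scale="size_normalized")


def to_fpkm(matrix: ExpressionMatrix, gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Fragments per kilobase per million on size-normalized counts.

    fpkm[i, j] = normalized[i, j] * 1e9 / (length_i * T_j) with T_j the
    normalized column total.
    """
    matrix._require("size_normalized", "to_fpkm")
    lengths = gene_lengths if gene_lengths is not None else matrix.gene_lengths
    if lengths is None:
        raise ExpressionError("gene lengths are required for FPKM")
    matrix = replace(matrix, gene_lengths=lengths)  # re-validates coverage/positivity
    lengths = matrix.gene_lengths.reindex(matrix.row_ids)
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        raise ExpressionError(f"zero column total for samples {list(totals.index[totals <= 0][:5])}")
    fpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return replace(matrix, values=fpkm, scale="fpkm")


def to_rpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million on size-normalized counts (no length normalization)."""
    matrix._require("size_normalized", "to_rpm")
    if matrix.gene_lengths is not None:
        raise ExpressionError("gene lengths are not applicable on the RPM path")
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        raise ExpressionError(f"zero column total for samples {list(totals.index[totals <= 0][:5])}")
    return replace(matrix, values=matrix.values.mul(1e6).div(totals, axis=1), scale="rpm")


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(1 + x) on an FPKM or RPM matrix."""
    if matrix.scale not in ("fpkm", "rpm"):
        raise ExpressionError(f"log2p1 applies to fpkm/rpm matrices, not {matrix.scale!r}")
    return replace(matrix, values=np.log2(1.0 + matrix.values), scale="log2p1")


@dataclass(frozen=True)
class FilterReport:
    kept_ids: tuple[str, ...]
    dropped_ids: tuple[str, ...]
    cumulative_fraction_at_cut: float
    threshold: float


def cumulative_abundance_filter(
    matrix: ExpressionMatrix, fraction: float = 0.99
) -> FilterReport:
    """Keep the most abundant rows reaching ``fraction`` of cumulative median expression.

    Rows are ranked by median across samples in descending order (ties by
    row id ascending) and the minimal prefix whose cumulative median sum
    reaches ``fraction`` of the total is kept, together with any rows tied
    at the cut median. Medians must be on a linear scale: a cumulative
    share of total expression is only meaningful additively.
    """
    if not (0 < fraction <= 1):
        raise ExpressionError(f"fraction must be in (0, 1], got {fraction}")
    if matrix.scale not in _LINEAR_SCALES:
        raise ExpressionError(
            f"cumulative abundance filter needs a linear scale, matrix is {matrix.scale!r}"
        )
    medians = matrix.values.median(axis=1)
    total = float(medians.sum())
    if total <= 0:
        raise ExpressionError("all rows have zero median expression")
    order = medians.to_frame("median").reset_index(names="row_id")
    order = order.sort_values(["median", "row_id"], ascending=[False, True], kind="mergesort")
    cum = order["median"].cumsum().to_numpy()
    target = fraction * total
    cut = int(np.searchsorted(cum, target - 1e-12 * total, side="left"))
    cut_median = order["median"].iloc[cut]
    keep_mask = np.zeros(len(order), dtype=bool)
    keep_mask[: cut + 1] = True
    keep_mask |= order["median"].to_numpy() == cut_median  # ties at the cut kept together
    kept = order.loc[keep_mask, "row_id"]
    dropped = order.loc[~keep_mask, "row_id"]
    return FilterReport(
        kept_ids=tuple(kept),
        dropped_ids=tuple(dropped),
        cumulative_fraction_at_cut=float(cum[keep_mask.nonzero()[0][-1]] / total),
        threshold=fraction,
    )


def expressed_above(
    matrix: ExpressionMatrix, gene_list: Sequence[str], threshold: float = 1.0
) -> tuple[list[str], list[str]]:
    """Partition ``gene_list`` by median log2(1+x) >= threshold (closed bound).

    Genes absent from the matrix count as not expressed. Order of
    ``gene_list`` is preserved in both partitions.
    """
    matrix._require("log2p1", "expressed_above")
    medians = matrix.values.median(axis=1)
    expressed, excluded = [], []
    for gene in gene_list:
        if gene in medians.index and medians[gene] >= threshold:
            expressed.append(gene)
        else:
            excluded.append(gene)
    return expressed, excluded


def read_counts_tsv(path: str | Path, scale: str = "raw_counts") -> ExpressionMatrix:
    """Read a TSV count matrix: first column row ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale)


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ExpressionError(f"{path}: expected columns gene_id, length_bp")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="length_bp")
    return s


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "sample_type" not in df.columns:
        raise ExpressionError(f"{path}: sample sheet needs sample_id and sample_type columns")
    return df


def select_samples(
    matrix: ExpressionMatrix, sheet: pd.DataFrame, sample_type: str
) -> ExpressionMatrix:
    """Subset a matrix to the samples of one sample_type, joined by id."""
    wanted = sheet.loc[sheet["sample_type"] == sample_type, "sample_id"]
    keep = matrix.sample_ids.intersection(pd.Index(wanted))
    if keep.empty:
        raise ExpressionError(f"no samples of type {sample_type!r} present in the matrix")
    return replace(matrix, values=matrix.values.loc[:, keep])
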