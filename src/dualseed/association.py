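"""miRNA-mRNA anticorrelation screening.

For each gene, expression across samples is correlated with the focal
miRNA's expression using Spearman's rank correlation (average ranks, so the
usual tie correction is implicit in the Pearson-of-ranks form). Two-sided
p-values for the zero-correlation null use the t approximation for n >= 10
and exact enumeration over rank permutations for smaller n. P-values are
adjusted with the Benjamini-Hochberg step-up procedure; a gene is called
significantly anticorrelated when rho < 0 and the adjusted p is below alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionError, ExpressionMatrix

__all__ = [
    "AssociationError",
    "GroupComparison",
    "spearman_table",
    "bh_adjust",
    "compare_groups",
    "significant_anticorrelated",
]

MIN_SHARED_SAMPLES = 5
EXACT_SPEARMAN_MAX_N = 9  # enumerate n! rank permutations below this sample count


class AssociationError(ValueError):
    """Invalid correlation input (samples, groups or p-values)."""


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation two-sided p for Spearman rho at small n."""
    rx = _rank(x)
    ry = _rank(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rho = float(rx_c @ ry_c) / denom
    hits = total = 0
    target = abs(float(rx_c @ ry_c)) - 1e-9 * denom
    for perm in permutations(ry_c):
        total += 1
        if abs(float(rx_c @ np.asarray(perm))) >= target:
            hits += 1
    return rho, hits / total


def spearman_table(
    mrna: ExpressionMatrix,
    mirna: pd.Series,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of mRNA expression with a miRNA vector.

    Samples are paired by shared id (never by column order). Genes with a
    constant expression vector -- or all genes, if the miRNA vector is
    constant -- have undefined rho; they are flagged ``excluded`` and left
    out of the BH family. Returns a frame indexed by gene id with columns
    ``rho``, ``p``, ``padj``, ``n``, ``excluded``.
    """
    mrna._require("log2p1", "spearman_table")
    shared = mrna.sample_ids.intersection(mirna.index)
    if len(shared) < MIN_SHARED_SAMPLES:
        raise AssociationError(
            f"only {len(shared)} shared samples between matrices; need >= {MIN_SHARED_SAMPLES}"
        )
    values = mrna.values.loc[genes if genes is not None else mrna.row_ids, shared]
    y = mirna.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    X = values.to_numpy(dtype=float)
    const_gene = np.ptp(X, axis=1) == 0
    const_y = np.ptp(y) == 0

    rho = np.full(len(values), np.nan)
    pval = np.full(len(values), np.nan)
    usable = ~const_gene if not const_y else np.zeros(len(values), dtype=bool)

    if usable.any():
        if n <= EXACT_SPEARMAN_MAX_N:
            for i in np.nonzero(usable)[0]:
                rho[i], pval[i] = _exact_spearman_p(X[i], y)
        else:
            rx = _rank(X[usable], axis=1)
            ry = _rank(y)
            rx_c = rx - rx.mean(axis=1, keepdims=True)
            ry_c = ry - ry.mean()
            num = rx_c @ ry_c
            denom = np.sqrt((rx_c**2).sum(axis=1) * float(ry_c @ ry_c))
            r = np.clip(num / denom, -1.0, 1.0)
            with np.errstate(divide="ignore"):
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            p[np.isinf(t)] = 0.0
            rho[usable] = r
            pval[usable] = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "rho": rho,
            "p": pval,
            "padj": np.nan,
            "n": n,
            "excluded": ~usable,
        },
        index=values.index.rename("gene_id"),
    )
    if usable.any():
        table.loc[usable, "padj"] = bh_adjust(pval[usable])
    return table


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_anticorrelated(
    table: pd.DataFrame, alpha: float = 0.05
) -> set[str]:
    """Genes with rho < 0 and BH-adjusted p < alpha."""
    mask = (~table["excluded"]) & (table["rho"] < 0) & (table["padj"] < alpha)
    return set(table.index[mask])


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of correlation values between two gene groups."""

    group_with: tuple[float, ...]
    group_without: tuple[float, ...]
    u_statistic: float
    p_two_sided: float
    stochastically_smaller: str  # "with", "without" or "neither"
    method: str


def compare_groups(
    table: pd.DataFrame,
    with_seed: set[str],
    without_seed: set[str],
) -> GroupComparison:
    """Compare rho distributions of genes with vs without a seed site.

    Uses the exact Mann-Whitney null when both groups have n <= 8 and the
    values are tie-free, otherwise the tie-corrected normal approximation.
    """
    if with_seed & without_seed:
        raise AssociationError("seed groups must be disjoint")
    sub = table[~table["excluded"]]
    a = sub.loc[sub.index.isin(with_seed), "rho"].to_numpy()
    b = sub.loc[sub.index.isin(without_seed), "rho"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise AssociationError("both groups need at least one correlation value")
    exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    # U_a = R_a - n_a(n_a+1)/2, so mean ranks recover which group sits lower
    mean_rank_a = res.statistic / len(a) + (len(a) + 1) / 2
    mean_rank_b = (len(a) * len(b) - res.statistic) / len(b) + (len(b) + 1) / 2
    if mean_rank_a < mean_rank_b:
        smaller = "with"
    elif mean_rank_b < mean_rank_a:
        smaller = "without"
    else:
        smaller = "neither"
    return GroupComparison(
        group_with=tuple(a),
        group_without=tuple(b),
        u_statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        stochastically_smaller=smaller,
        method=method,
    )
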