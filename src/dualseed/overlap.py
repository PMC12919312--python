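"""Targetome overlap and enrichment statistics.

Overlap between a canonical miRNA's targetome (genes with a 6mer site) and
a 5'-isomiR's targetome (genes with the shifted 7mer-m8 site) is measured
with the Jaccard index |A n B| / |A u B|. Enrichment of a gene property
within a focal gene set over an explicit universe uses the sample odds
ratio (a*d)/(b*c) and the two-sided Fisher exact test (point-probability
rule). Extension ratios quantify how often canonical 6mer sites sit inside
the longer contiguous site that also matches the isomiR seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ExtensionStats

__all__ = [
    "OverlapError",
    "ContingencyTable",
    "OverlapResult",
    "jaccard_index",
    "overlap_profile",
    "build_enrichment_table",
    "odds_ratio_fisher",
    "percentile_rank",
]


class OverlapError(ValueError):
    """Invalid sets, universe or contingency table."""


def jaccard_index(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A n B| / |A u B|; NaN when both sets are empty (undefined)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return math.nan
    return len(a & b) / len(union)


@dataclass(frozen=True)
class OverlapResult:
    """Canonical-vs-isomiR targetome overlap for one miRNA."""

    mirna_label: str
    shift5: int
    n_6mer: int
    n_7mer_m8: int
    n_intersection: int
    n_union: int
    jaccard: float
    n_6mer_sites: int | None = None
    n_extendable_sites: int | None = None
    extension_ratio_sites: float | None = None
    n_genes_with_extendable: int | None = None
    extension_ratio_genes: float | None = None

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_6mer, self.n_7mer_m8):
            raise OverlapError("intersection larger than one of the sets")
        if self.n_union != self.n_6mer + self.n_7mer_m8 - self.n_intersection:
            raise OverlapError("inclusion-exclusion violated")


def overlap_profile(
    mirna_label: str,
    shift5: int,
    canonical_targets: Iterable[str],
    isomir_targets: Iterable[str],
    extension: ExtensionStats | None = None,
) -> OverlapResult:
    """Fill an :class:`OverlapResult` from two target sets (+ optional extension stats).

    Extension ratios are reported at both granularities: extendable sites /
    all canonical 6mer sites, and genes with >= 1 extendable site / genes
    with >= 1 canonical site.
    """
    a, b = set(canonical_targets), set(isomir_targets)
    inter, union = len(a & b), len(a | b)
    kwargs = {}
    if extension is not None:
        kwargs = dict(
            n_6mer_sites=extension.n_sites,
            n_extendable_sites=extension.n_extendable_sites,
            extension_ratio_sites=extension.site_ratio,
            n_genes_with_extendable=extension.n_genes_with_extendable,
            extension_ratio_genes=extension.gene_ratio,
        )
    return OverlapResult(
        mirna_label=mirna_label,
        shift5=shift5,
        n_6mer=len(a),
        n_7mer_m8=len(b),
        n_intersection=inter,
        n_union=union,
        jaccard=inter / union if union else math.nan,
        **kwargs,
    )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table over an explicit gene universe.

    Rows: in the focal set / not; columns: has the property / not.
    """

    a: int  # focal & property
    b: int  # focal & not property
    c: int  # not focal & property
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise OverlapError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_enrichment_table(
    focal_genes: Iterable[str],
    property_genes: Iterable[str],
    universe: Iterable[str],
) -> ContingencyTable:
    focal, prop, uni = set(focal_genes), set(property_genes), set(universe)
    stray = sorted(focal - uni)
    if stray:
        raise OverlapError(f"focal genes outside the universe: {stray[:10]}")
    stray = sorted(prop - uni)
    if stray:
        raise OverlapError(f"property genes outside the universe: {stray[:10]}")
    a = len(focal & prop)
    b = len(focal - prop)
    c = len(prop - focal)
    d = len(uni) - a - b - c
    return ContingencyTable(a, b, c, d)


def odds_ratio_fisher(table: ContingencyTable) -> tuple[float, float]:
    """Sample odds ratio (a*d)/(b*c) and two-sided Fisher exact p.

    The odds ratio is +inf when b*c == 0 with a*d > 0, and NaN for a
    degenerate table with both products zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return odds, float(p)


def percentile_rank(value: float, reference_values: Sequence[float]) -> float:
    """100 x fraction of reference values <= value."""
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise OverlapError("empty reference for percentile rank")
    return 100.0 * float(np.mean(ref <= value))


def overlap_results_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Ranked overlap table in the supplementary-schema column layout."""
    df = pd.DataFrame(
        [
            {
                "mirna": r.mirna_label,
                "shift5": r.shift5,
                "6mer": r.n_6mer,
                "7mer-m8": r.n_7mer_m8,
                "intersection": r.n_intersection,
                "union": r.n_union,
                "jaccard": r.jaccard,
            }
            for r in results
        ]
    )
    return df.sort_values(["jaccard", "mirna"], ascending=[False, True]).reset_index(drop=True)


def extension_results_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "mirna": r.mirna_label,
                "6mer_sites": r.n_6mer_sites,
                "extended_sites": r.n_extendable_sites,
                "site_ratio": r.extension_ratio_sites,
                "6mer_genes": r.n_6mer,
                "extended_genes": r.n_genes_with_extendable,
                "gene_ratio": r.extension_ratio_genes,
            }
            for r in results
            if r.n_6mer_sites is not None
        ]
    )
    return df.sort_values(["site_ratio", "mirna"], ascending=[False, True]).reset_index(drop=True)
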