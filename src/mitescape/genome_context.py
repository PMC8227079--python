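"""Genomic-context categorization of MITE copies and enrichment statistics.

Every copy receives exactly one category, evaluated in priority order against
all gene models on its contig:

1. five_prime_utr  -- overlaps an annotated 5'UTR
2. three_prime_utr -- overlaps an annotated 3'UTR
3. cds             -- overlaps an annotated CDS
4. intron          -- fully contained in an intron
5. upstream        -- within 1 kb upstream of a gene start (strand-aware)
6. downstream      -- within 1 kb downstream of a gene end (strand-aware)
7. intergenic      -- none of the above

UTR/CDS require any overlap while intron requires full containment; a copy
straddling an intron/exon boundary therefore falls through to the next rule.
"Within 1 kb" is inclusive (edge-to-edge gap <= 1000 bp). A copy near several
genes takes the highest-priority category over all of them; ties at equal
priority go to the nearest gene edge.

The group x category table feeds a Pearson chi-squared test with per-cell
contributions (O-E)^2/E, the quantities behind the enrichment balloon plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, ParameterError, UnknownReferenceError
from .seqio import GeneModel, Interval

CATEGORIES = ("five_prime_utr", "three_prime_utr", "cds", "intron",
              "upstream", "downstream", "intergenic")

#: categories tied to a specific gene (everything but intergenic)
GENE_LINKED = CATEGORIES[:-1]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    contributions: pd.DataFrame  # (O-E)^2 / E per cell
    signs: pd.DataFrame          # sign(O-E) per cell
    expected: pd.DataFrame


def _overlaps_any(iv: Interval, features: Sequence[Interval]) -> bool:
    return any(iv.start < f.end and f.start < iv.end for f in features)


def _contained_in_any(iv: Interval, features: Sequence[Interval]) -> bool:
    return any(f.start <= iv.start and iv.end <= f.end for f in features)


def _gene_category(iv: Interval, gene: GeneModel,
                   window: int) -> tuple[int, int] | None:
    """(priority index, distance) of the best category of ``iv`` w.r.t. one
    gene, or None."""
    if _overlaps_any(iv, gene.five_prime_utrs):
        return 0, 0
    if _overlaps_any(iv, gene.three_prime_utrs):
        return 1, 0
    if _overlaps_any(iv, gene.cds):
        return 2, 0
    if _contained_in_any(iv, gene.introns):
        return 3, 0
    # strand-aware flanks: upstream of a minus-strand gene is the
    # higher-coordinate side
    if gene.strand == "-":
        up_gap = iv.start - gene.end   # region right of the gene
        down_gap = gene.start - iv.end
    else:
        up_gap = gene.start - iv.end
        down_gap = iv.start - gene.end
    if 0 <= up_gap <= window:
        return 4, up_gap
    if 0 <= down_gap <= window:
        return 5, down_gap
    return None


def categorize_copy(copy, genes: Iterable[GeneModel], window: int = 1000,
                    contig_lengths: Mapping[str, int] | None = None) -> str:
    """Context category of one copy (anything with contig/start/end attrs)."""
    if contig_lengths is not None and copy.contig not in contig_lengths:
        raise UnknownReferenceError(f"unknown contig {copy.contig!r}")
    iv = Interval(copy.contig, copy.start, copy.end)
    best: tuple[int, int] | None = None
    for gene in genes:
        if gene.contig != copy.contig:
            continue
        cat = _gene_category(iv, gene, window)
        if cat is not None and (best is None or cat < best):
            best = cat
    return CATEGORIES[best[0]] if best is not None else "intergenic"


def assign_gene(copy, genes: Iterable[GeneModel], window: int = 1000) -> str | None:
    """Id of the gene carrying/neighbouring the copy (None if intergenic)."""
    iv = Interval(copy.contig, copy.start, copy.end)
    best = None
    best_gene = None
    for gene in genes:
        if gene.contig != copy.contig:
            continue
        cat = _gene_category(iv, gene, window)
        if cat is not None and (best is None or cat < best):
            best, best_gene = cat, gene.gene_id
    return best_gene


def localization_table(labeled: Iterable[tuple[str, str]],
                       groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts per (group, category) from (group, category) pairs.

    Rows are groups, columns the seven categories; a Total row and a Total
    column (margins) are appended.
    """
    pairs = list(labeled)
    if groups is None:
        groups = sorted({g for g, _ in pairs})
    table = pd.DataFrame(0, index=list(groups), columns=list(CATEGORIES),
                         dtype=int)
    for group, category in pairs:
        if category not in CATEGORIES:
            raise ParameterError(f"unknown category {category!r}")
        table.loc[group, category] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def _strip_margins(table: pd.DataFrame) -> pd.DataFrame:
    core = table
    if "Total" in core.index:
        core = core.drop(index="Total")
    if "Total" in core.columns:
        core = core.drop(columns="Total")
    return core


def enrichment_chisq(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a group x category table.

    E = row total x column total / grand total; the statistic is the sum of
    the per-cell contributions (O-E)^2/E, df = (rows-1)(cols-1). Margins
    ("Total" row/column), if present, are ignored, and all-zero rows/columns
    (categories or groups never observed) are dropped before testing.
    """
    core = _strip_margins(table)
    core = core.loc[(core.sum(axis=1) > 0), (core.sum(axis=0) > 0)]
    obs = core.to_numpy(dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any() or total == 0:
        raise DegenerateTableError("zero margin in contingency table")
    expected = row @ col / total
    contrib = (obs - expected) ** 2 / expected
    statistic = float(contrib.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    pvalue = float(stats.chi2.sf(statistic, df))
    idx, cols = core.index, core.columns
    return ChiSquareResult(
        statistic=statistic, df=df, pvalue=pvalue,
        contributions=pd.DataFrame(contrib, index=idx, columns=cols),
        signs=pd.DataFrame(np.sign(obs - expected).astype(int), index=idx,
                           columns=cols),
        expected=pd.DataFrame(expected, index=idx, columns=cols))


def genic_fraction(table: pd.DataFrame, rounded: bool = False) -> float:
    """Percent of copies in genic regions: 100 x (total - intergenic) / total.

    Genic = gene body plus the 1 kb up/downstream windows, i.e. every
    category except intergenic.
    """
    core = _strip_margins(table)
    total = int(core.to_numpy().sum())
    if total == 0:
        raise DegenerateTableError("empty localization table")
    intergenic = int(core["intergenic"].sum())
    pct = 100.0 * (total - intergenic) / total
    return float(round(pct)) if rounded else pct
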