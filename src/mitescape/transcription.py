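"""Co-transcription analysis of MITE copies.

Reads are matched to MITE copy sequences with local alignment; matches longer
than 20 bp at more than 80% identity count as evidence. Copies gathering at
least ten matching reads (summed over libraries by default) are treated as
co-transcribed and joined to their host or neighbouring gene through the
genomic-context category. Expression of the MITE segment and of the whole
gene is put on a common scale as normalized RPK,

    RPK            = count / (feature length / 1000)
    normalized RPK = RPK / (library size / 1e6)

and their ratio M/g flags genes whose MITE-derived segment is preferentially
expressed: a record is selected when the gene's normalized RPK exceeds 1 and
M/g exceeds 1.9 (both strict). Genes whose M/g range across libraries exceeds
1.5 are candidates for tissue-specific isoform usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from . import align
from .errors import ParameterError
from .genome_context import GENE_LINKED

MIN_MATCH_LEN = 20       # exclusive: matches must be longer than this
MIN_MATCH_IDENTITY = 80.0  # exclusive
MIN_READS = 10           # inclusive: >= 10 reads -> co-transcribed
MIN_GENE_RPK = 1.0       # exclusive
MIN_MG = 1.9             # exclusive
MIN_MG_RANGE = 1.5       # exclusive


@dataclass(frozen=True)
class ReadMatch:
    read: str
    mite: str
    length: int
    identity: float


def match_reads_to_mites(reads: Mapping[str, str], mite_seqs: Mapping[str, str],
                         min_len: int = MIN_MATCH_LEN,
                         min_identity: float = MIN_MATCH_IDENTITY,
                         ) -> list[ReadMatch]:
    """Best local match per (read, MITE copy); kept when longer than
    ``min_len`` at identity above ``min_identity`` (both strict). Each read
    counts at most once per copy."""
    matches: list[ReadMatch] = []
    for rname, rseq in reads.items():
        if len(rseq) < min_len:
            continue
        for mname, mseq in mite_seqs.items():
            best = None
            for target in (mseq, align.revcomp(mseq)):
                a = align.best_local_alignment(rseq, target)
                if best is None or a.score > best.score:
                    best = a
            if best.length > min_len and best.identity > min_identity:
                matches.append(ReadMatch(rname, mname, best.length,
                                         best.identity))
    return matches


def evidence_counts(matches: Iterable[ReadMatch]) -> pd.Series:
    """Matched-read count per MITE copy."""
    df = pd.DataFrame([(m.mite,) for m in matches], columns=["mite"])
    if df.empty:
        return pd.Series(dtype=int, name="reads")
    return df.value_counts("mite").rename("reads")


def cotranscribed_mites(read_counts: Mapping[str, int] | pd.Series,
                        categories: Mapping[str, str],
                        copy_gene: Mapping[str, str | None],
                        min_reads: int = MIN_READS) -> pd.DataFrame:
    """Co-transcribed copies joined to their host/neighbouring gene.

    ``read_counts`` are per-copy totals (summed over libraries); copies with
    >= min_reads whose context category is gene-linked (not intergenic) are
    returned with their gene id.
    """
    rows = []
    counts = dict(read_counts.items() if hasattr(read_counts, "items")
                  else read_counts)
    for copy_id, n in counts.items():
        if n < min_reads:
            continue
        category = categories.get(copy_id, "intergenic")
        if category not in GENE_LINKED:
            continue
        gene = copy_gene.get(copy_id)
        if gene is None:
            continue
        rows.append({"mite": copy_id, "gene": gene, "category": category,
                     "reads": int(n)})
    return pd.DataFrame(rows, columns=["mite", "gene", "category", "reads"])


def normalized_rpk(count: float, length_bp: float, library_size: float) -> float:
    """(count / (length/1000)) / (library size / 1e6)."""
    if length_bp <= 0:
        raise ParameterError("feature length must be > 0")
    if library_size <= 0:
        raise ParameterError("library size must be > 0")
    rpk = count / (length_bp / 1000.0)
    return rpk / (library_size / 1_000_000.0)


def mg_ratio(pairs: pd.DataFrame, counts: pd.DataFrame,
             feature_lengths: Mapping[str, int],
             library_sizes: Mapping[str, int],
             min_gene_rpk: float = MIN_GENE_RPK,
             min_mg: float = MIN_MG) -> pd.DataFrame:
    """Per gene x MITE x library M/g records.

    ``pairs`` needs columns (gene, mite); ``counts`` columns
    (feature_id, library, count). The gene denominator uses all reads counted
    on the gene feature, MITE segment included. Selected requires gene
    normalized RPK > min_gene_rpk and M/g > min_mg (strict); a zero gene RPK
    leaves the ratio undefined (NaN) and unselected.
    """
    cmap = counts.set_index(["feature_id", "library"])["count"]
    rows = []
    for _, pair in pairs.iterrows():
        gene, mite = pair["gene"], pair["mite"]
        for fid in (gene, mite):
            if fid not in feature_lengths:
                raise ParameterError(f"unknown feature id {fid!r}")
        for lib, size in library_sizes.items():
            g_count = float(cmap.get((gene, lib), 0))
            m_count = float(cmap.get((mite, lib), 0))
            g = normalized_rpk(g_count, feature_lengths[gene], size)
            m = normalized_rpk(m_count, feature_lengths[mite], size)
            mg = m / g if g > 0 else float("nan")
            selected = g > min_gene_rpk and g > 0 and mg > min_mg
            rows.append({"gene": gene, "mite": mite, "library": lib,
                         "gene_rpk": g, "mite_rpk": m, "mg": mg,
                         "selected": bool(selected)})
    return pd.DataFrame(rows, columns=["gene", "mite", "library", "gene_rpk",
                                       "mite_rpk", "mg", "selected"])


def differential_mg(mg_records: pd.DataFrame,
                    min_range: float = MIN_MG_RANGE) -> set[str]:
    """Genes whose M/g spread across libraries exceeds ``min_range``.

    Only defined (non-NaN) ratios are considered; genes observed in fewer
    than two libraries are not evaluable and are excluded.
    """
    out: set[str] = set()
    if mg_records.empty:
        return out
    valid = mg_records.dropna(subset=["mg"])
    for gene, sub in valid.groupby("gene"):
        if sub["library"].nunique() < 2:
            continue
        if sub["mg"].max() - sub["mg"].min() > min_range:
            out.add(str(gene))
    return out


def mg_matrix(mg_records: pd.DataFrame) -> pd.DataFrame:
    """Gene x library matrix of M/g values (heat-map input)."""
    return mg_records.pivot_table(index="gene", columns="library", values="mg",
                                  aggfunc="max")
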