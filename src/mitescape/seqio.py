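"""Sequence / annotation I/O with explicit coordinate conventions.

All in-memory coordinates are 0-based half-open. GFF3 is read and written with
its native 1-based closed convention; BED with 0-based half-open. Sequences are
normalised to uppercase on read, and any symbol outside ACGTN becomes N (which
never matches in alignments).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .errors import FastaParseError, Gff3StructureError, ParameterError, UnknownReferenceError

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.contig == other.contig
                and self.start < other.end and other.start < self.end)


@dataclass
class GeneModel:
    """One gene collapsed over isoforms.

    Exon / CDS / UTR interval lists are unions over all mRNAs of the gene
    (the localization analysis categorizes per gene, not per isoform).
    Introns are the gaps between the merged exons.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    five_prime_utrs: list[Interval] = field(default_factory=list)
    three_prime_utrs: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.exons)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.exons)

    @property
    def introns(self) -> list[Interval]:
        merged = merge_intervals(self.exons)
        out = []
        for a, b in zip(merged, merged[1:]):
            if b.start > a.end:
                out.append(Interval(self.contig, a.end, b.start, self.strand))
        return out

    def validate(self) -> None:
        exon_union = merge_intervals(self.exons)
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in exon_union):
                raise Gff3StructureError(
                    f"CDS [{c.start},{c.end}) of {self.gene_id} outside exon union")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals (same contig assumed), sorted and merged."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = Interval(last.contig, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} dict.

    Non-ACGTN symbols are normalised to N. Raises FastaParseError with the
    line number for sequence data appearing before any header.
    """
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = _normalise("".join(chunks))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaParseError("empty FASTA header", lineno)
                if name in seqs:
                    raise FastaParseError(f"duplicate record id {name!r}", lineno)
                chunks = []
            else:
                if name is None:
                    raise FastaParseError("sequence data before first header", lineno)
                chunks.append(line)
    if name is not None:
        seqs[name] = _normalise("".join(chunks))
    return seqs


def _normalise(seq: str) -> str:
    return _NON_ACGTN.sub("N", seq.upper())


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_UTR5_TYPES = {"five_prime_UTR", "5'UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR", "three_prime_utr"}


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based closed) into 0-based half-open.

    For genes with multiple mRNAs the union model over isoforms is used.
    Orphan children and CDS outside the exon union raise Gff3StructureError.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique", force=True)
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise Gff3StructureError(
                    f"feature {feat.id or feat.featuretype} references unknown "
                    f"parent {parent_id!r}")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand)
        for feat in db.children(gene):
            iv = Interval(feat.seqid, feat.start - 1, feat.end, gene.strand)
            if feat.featuretype == "exon":
                model.exons.append(iv)
            elif feat.featuretype == "CDS":
                model.cds.append(iv)
            elif feat.featuretype in _UTR5_TYPES:
                model.five_prime_utrs.append(iv)
            elif feat.featuretype in _UTR3_TYPES:
                model.three_prime_utrs.append(iv)
        if not model.exons:
            # gene with no exon children: treat its span as a single exon
            model.exons.append(Interval(gene.seqid, gene.start - 1, gene.end,
                                        gene.strand))
        model.exons = merge_intervals(model.exons)
        model.cds = merge_intervals(model.cds)
        model.five_prime_utrs = merge_intervals(model.five_prime_utrs)
        model.three_prime_utrs = merge_intervals(model.three_prime_utrs)
        model.validate()
        genes.append(model)
    return genes


def write_gene_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR; one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            rna_id = f"{g.gene_id}.t1"
            fh.write(_gff_line(g.contig, "gene", g.start, g.end, g.strand,
                               f"ID={g.gene_id}"))
            fh.write(_gff_line(g.contig, "mRNA", g.start, g.end, g.strand,
                               f"ID={rna_id};Parent={g.gene_id}"))
            for ftype, ivs in (("exon", g.exons), ("CDS", g.cds),
                               ("five_prime_UTR", g.five_prime_utrs),
                               ("three_prime_UTR", g.three_prime_utrs)):
                for iv in ivs:
                    fh.write(_gff_line(g.contig, ftype, iv.start, iv.end,
                                       g.strand, f"Parent={rna_id}"))


def _gff_line(contig: str, ftype: str, start0: int, end0: int, strand: str,
              attrs: str, source: str = "mitescape", score: str = ".") -> str:
    return (f"{contig}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t{score}\t"
            f"{strand}\t.\t{attrs}\n")


def write_mite_gff3(copies, path: str | Path) -> None:
    """Write accepted MITE copies as GFF3 'MITE' features (1-based closed).

    Attributes carry family, superfamily (when annotated), percent identity
    and the called TSD.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for idx, c in enumerate(copies, start=1):
            attrs = [f"ID=MITE{idx:06d}", f"family={c.family}"]
            sf = getattr(c, "superfamily", None)
            if sf:
                attrs.append(f"superfamily={sf}")
            tsd = getattr(c, "tsd", None)
            if tsd:
                attrs.append(f"tsd={tsd}")
            fh.write(_gff_line(c.contig, "MITE", c.start, c.end, c.strand,
                               ";".join(attrs),
                               score=f"{c.identity:.1f}"))


def write_bed6(copies, path: str | Path) -> None:
    """BED6 (0-based half-open): name = family, score = integer identity."""
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.family}\t"
                     f"{round(c.identity)}\t{c.strand}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def extend_intervals(intervals: Iterable[Interval], pad: int,
                     contig_lengths: Mapping[str, int]) -> list[Interval]:
    """Grow each interval by ``pad`` on both sides, clipped to its contig."""
    if pad < 0:
        raise ParameterError("pad must be >= 0")
    out = []
    for iv in intervals:
        if iv.contig not in contig_lengths:
            raise UnknownReferenceError(f"unknown contig {iv.contig!r}")
        length = contig_lengths[iv.contig]
        out.append(Interval(iv.contig, max(0, iv.start - pad),
                            min(length, iv.end + pad), iv.strand))
    return out
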