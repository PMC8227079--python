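"""Genome-wide detection of full-length MITE copies.

Each family consensus is scanned against every contig on both strands with the
seeded Smith--Waterman engine; raw alignments are then filtered with the
80-80-80 rule (>=80% identity, >=80 bp, covering >=80% of the consensus) plus
end anchoring: the alignment must start within the first 10 bases of the
consensus and end within the last 10, i.e. similarity continues over the whole
query. Overlapping accepted copies from different families are resolved by an
identity x coverage score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from . import align
from .errors import ParameterError

#: minimum consensus length the scanner accepts
MIN_CONSENSUS_LEN = 50


@dataclass(frozen=True)
class AlignmentHit:
    """One raw local alignment of a consensus against the genome.

    Subject span is 0-based half-open on the forward strand of the contig;
    the query span is 1-based inclusive on the consensus (forward
    orientation regardless of hit strand).
    """

    family: str
    contig: str
    start: int
    end: int
    strand: str
    query_start: int
    query_end: int
    identity: float
    length: int
    score: int


@dataclass(frozen=True)
class CopyHit:
    """An alignment hit judged against the full-length acceptance rules."""

    family: str
    contig: str
    start: int
    end: int
    strand: str
    query_start: int
    query_end: int
    identity: float
    length: int
    score: int
    consensus_length: int
    left_offset: int
    right_offset: int
    accepted: bool
    reason: str  # "" when accepted

    @property
    def coverage(self) -> float:
        """Alignment length as a fraction of the consensus length."""
        return self.length / self.consensus_length


def local_align_all(family: str, consensus: str, genome: Mapping[str, str],
                    min_identity: float = 80.0, min_len: int = 80,
                    seed_k: int = 11) -> list[AlignmentHit]:
    """Every maximal local alignment of ``consensus`` in ``genome``.

    Both strands are scanned; minus-strand hits report forward-genome subject
    coordinates with strand "-" and query spans mapped back to the forward
    consensus orientation.
    """
    if not consensus:
        raise ParameterError("empty consensus")
    if len(consensus) < MIN_CONSENSUS_LEN:
        raise ParameterError(
            f"consensus shorter than {MIN_CONSENSUS_LEN} bp ({len(consensus)})")
    L = len(consensus)
    hits: list[AlignmentHit] = []
    for contig, seq in genome.items():
        for strand, query in (("+", consensus), ("-", align.revcomp(consensus))):
            for w_start, w_end in align.seed_windows(query, seq, k=seed_k):
                window = seq[w_start:w_end]
                for a in align.extract_local_alignments(
                        query, window, min_identity, min_len):
                    if strand == "+":
                        qs, qe = a.q_start + 1, a.q_end
                    else:
                        qs, qe = L - a.q_end + 1, L - a.q_start
                    hits.append(AlignmentHit(
                        family=family, contig=contig,
                        start=w_start + a.t_start, end=w_start + a.t_end,
                        strand=strand, query_start=qs, query_end=qe,
                        identity=a.identity, length=a.length, score=a.score))
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.strand))
    return _dedupe(hits)


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop identical hits that adjacent seed windows may both have produced."""
    seen = set()
    out = []
    for h in hits:
        key = (h.contig, h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def filter_full_length(hits: Iterable[AlignmentHit], consensus_length: int,
                       min_identity: float = 80.0, min_len: int = 80,
                       min_coverage: float = 0.8,
                       max_end_offset: int = 10) -> list[CopyHit]:
    """Apply 80-80-80 + end-anchoring acceptance to raw hits of one family.

    Offsets are 1-based distances from each consensus end to the first/last
    aligned query position; offset 1 means the alignment reaches the terminal
    base. Rejected hits are kept with ``accepted=False`` and a reason code
    ("identity", "length", "coverage" or "end_anchor"; first failing rule in
    that order).
    """
    out: list[CopyHit] = []
    for h in hits:
        left = h.query_start
        right = consensus_length - h.query_end + 1
        reason = ""
        if h.identity < min_identity:
            reason = "identity"
        elif h.length < min_len:
            reason = "length"
        elif h.length < min_coverage * consensus_length:
            reason = "coverage"
        elif left > max_end_offset or right > max_end_offset:
            reason = "end_anchor"
        out.append(CopyHit(
            family=h.family, contig=h.contig, start=h.start, end=h.end,
            strand=h.strand, query_start=h.query_start, query_end=h.query_end,
            identity=h.identity, length=h.length, score=h.score,
            consensus_length=consensus_length, left_offset=left,
            right_offset=right, accepted=(reason == ""), reason=reason))
    return out


def resolve_overlaps(copies: Iterable[CopyHit],
                     max_overlap: float = 0.5) -> list[CopyHit]:
    """Resolve competing accepted copies from different families.

    Among copies whose spans overlap by more than ``max_overlap`` of the
    shorter span, the one with the highest identity x coverage is kept; exact
    ties go to the lexicographically smaller family name. Output sorted by
    (contig, start).
    """
    pool = [c for c in copies if c.accepted]
    # rank: better score first, then family name for deterministic ties
    ranked = sorted(pool, key=lambda c: (-c.identity * c.coverage, c.family,
                                         c.contig, c.start))
    kept: list[CopyHit] = []
    for c in ranked:
        clash = False
        for k in kept:
            if k.contig != c.contig:
                continue
            ov = min(c.end, k.end) - max(c.start, k.start)
            if ov > max_overlap * min(c.end - c.start, k.end - k.start):
                clash = True
                break
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.contig, c.start, c.end))
    return kept


def find_copies(library: Mapping[str, str], genome: Mapping[str, str],
                min_identity: float = 80.0, min_len: int = 80,
                min_coverage: float = 0.8, max_end_offset: int = 10,
                seed_k: int = 11) -> dict[str, list[CopyHit]]:
    """Scan every family of a consensus library; returns per-family CopyHits
    (accepted and rejected). Use :func:`resolve_overlaps` on the accepted
    union for the final non-redundant annotation."""
    out: dict[str, list[CopyHit]] = {}
    for family, consensus in library.items():
        hits = local_align_all(family, consensus, genome,
                               min_identity=min_identity, min_len=min_len,
                               seed_k=seed_k)
        out[family] = filter_full_length(
            hits, len(consensus), min_identity=min_identity, min_len=min_len,
            min_coverage=min_coverage, max_end_offset=max_end_offset)
    return out


def annotate(copy: CopyHit, **fields) -> CopyHit:
    """Return a copy of ``copy`` with extra dataclass fields replaced."""
    return replace(copy, **fields)
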