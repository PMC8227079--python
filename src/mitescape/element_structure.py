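"""Structural characterisation of MITE copies.

From each full-length copy and its 50-nt flanks this module calls the target
site duplication (TSD), the terminal inverted repeat (TIR), and maps the pair
to a Class II superfamily:

====================  =======================
TSD                   superfamily
====================  =======================
TA (2 bp)             Stowaway (Tc1/mariner)
TAA / TTA (3 bp)      Tourist (PIF/Harbinger)
8 bp                  hAT-like
9-10 bp               Mutator-like
(TA)n flank, weak TIR MiM (Mutator-like group)
====================  =======================

MiMs -- MITEs inserted in microsatellites -- sit inside (TA)n stretches and
carry distinguishable but poorly conserved TIRs; they are reported under the
Mutator-like group in summary tables. The module also clusters consensus
sequences into families with the 80-80-80 rule (single linkage) and mines
putative autonomous Mutator partners around transposase hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from . import align
from .copyfinder import CopyHit
from .errors import ParameterError
from .seqio import Interval

SUPERFAMILIES = ("Stowaway", "Tourist", "hAT-like", "Mutator-like", "MiM",
                 "Unclassified")

#: TSD lengths probed, longest first so the most informative call wins
TSD_LENGTHS = (10, 9, 8, 3, 2)

#: group used in summary tables (MiM counts within the Mutator-like group)
GROUP_OF = {label: ("Mutator-like" if label == "MiM" else label)
            for label in SUPERFAMILIES}


@dataclass(frozen=True)
class FlankPair:
    """Element sequence with its immediate flanks (<= 50 nt, shorter at contig
    edges)."""

    left_flank: str
    right_flank: str
    element: str


@dataclass(frozen=True)
class TsdCall:
    tsd: str
    k: int  # 0 = no call
    exact: bool
    ta_stretch: bool


@dataclass(frozen=True)
class TirCall:
    arm: int  # 0 = no call
    identity: float

    @property
    def recognized(self) -> bool:
        return self.arm >= 10 and self.identity >= 80.0


@dataclass(frozen=True)
class AutonomousElement:
    """Putative autonomous element: transposase hit plus inverted-repeat
    boundaries. ``start``/``end`` are None when no arm pair was found
    (candidate-without-boundaries)."""

    contig: str
    transposase_start: int
    transposase_end: int
    start: int | None
    end: int | None
    tir_arm: int
    tir_identity: float

    @property
    def has_boundaries(self) -> bool:
        return self.start is not None

    @property
    def sequence_span(self) -> tuple[int, int]:
        if self.has_boundaries:
            return self.start, self.end
        return self.transposase_start, self.transposase_end


@dataclass
class StructuredCopy:
    """A copy joined with its structural calls; the pipeline's per-copy row."""

    copy: CopyHit
    tsd: TsdCall
    tir: TirCall
    superfamily: str

    # convenience pass-throughs used by the GFF3/BED writers
    @property
    def family(self):
        return self.copy.family

    @property
    def contig(self):
        return self.copy.contig

    @property
    def start(self):
        return self.copy.start

    @property
    def end(self):
        return self.copy.end

    @property
    def strand(self):
        return self.copy.strand

    @property
    def identity(self):
        return self.copy.identity

    @property
    def group(self) -> str:
        return GROUP_OF[self.superfamily]


# ---------------------------------------------------------------------------
# TSD / TIR calls


def extract_flanks(genome: Mapping[str, str], copy: CopyHit,
                   flank: int = 50) -> FlankPair:
    seq = genome[copy.contig]
    return FlankPair(
        left_flank=seq[max(0, copy.start - flank): copy.start],
        right_flank=seq[copy.end: copy.end + flank],
        element=seq[copy.start: copy.end])


def _is_ta_run(hexamer: str) -> bool:
    return hexamer in ("TATATA", "ATATAT")


def detect_tsd(flanks: FlankPair, lengths: Sequence[int] = TSD_LENGTHS) -> TsdCall:
    """Call the TSD by comparing element-adjacent k-mers of the two flanks.

    Longest k first; the first exact match wins. Only when no exact match
    exists at any probed length is a single mismatch tolerated for k >= 8
    (reported with ``exact=False``) -- checking tolerant long k-mers before
    exact short ones would let chance near-matches shadow a genuine short
    TSD. ``ta_stretch`` flags elements whose adjacent hexamer on either side
    is a (TA)3 run.
    """
    left, right = flanks.left_flank, flanks.right_flank
    ta = (_is_ta_run(left[-6:]) or _is_ta_run(right[:6]))
    if len(left) < 2 or len(right) < 2:
        return TsdCall("", 0, False, ta)

    def kmers(k):
        if len(left) < k or len(right) < k:
            return None
        lmer, rmer = left[-k:], right[:k]
        if "N" in lmer or "N" in rmer:
            return None
        return lmer, rmer

    for k in lengths:
        pair = kmers(k)
        if pair and pair[0] == pair[1]:
            return TsdCall(pair[0], k, True, ta)
    for k in lengths:
        if k < 8:
            continue
        pair = kmers(k)
        if pair and sum(a != b for a, b in zip(*pair)) == 1:
            return TsdCall(pair[0], k, False, ta)
    return TsdCall("", 0, False, ta)


def detect_tir(element: str, max_arm: int = 50, min_arm: int = 8) -> TirCall:
    """Find the arm length maximising ungapped identity between the leading arm
    and the reverse complement of the trailing arm.

    Ties go to the longer arm. Elements shorter than 2*min_arm get no call.
    """
    L = len(element)
    if L < 2 * min_arm:
        return TirCall(0, 0.0)
    best_arm, best_id = 0, -1.0
    for arm in range(min_arm, min(max_arm, L // 2) + 1):
        lead = element[:arm]
        trail_rc = align.revcomp(element[-arm:])
        matches = sum(a == b and a != "N" for a, b in zip(lead, trail_rc))
        ident = 100.0 * matches / arm
        if ident >= best_id:  # >= : prefer the longest arm at equal identity
            best_arm, best_id = arm, ident
    return TirCall(best_arm, best_id)


def classify_superfamily(tsd: TsdCall, tir: TirCall) -> str:
    """Map TSD/TIR calls to a superfamily label.

    The MiM rule (element in a (TA)n stretch with a weak or absent TIR) takes
    priority: such elements would otherwise be mis-read as Stowaways through
    the TA dinucleotide their microsatellite flanks always present.
    """
    if tsd.ta_stretch and tir.identity < 80.0:
        return "MiM"
    if tsd.k == 2 and tsd.tsd == "TA":
        return "Stowaway"
    if tsd.k == 3 and tsd.tsd in ("TAA", "TTA"):
        return "Tourist"
    if tsd.k == 8:
        return "hAT-like"
    if tsd.k in (9, 10):
        return "Mutator-like"
    return "Unclassified"


def structure_copies(genome: Mapping[str, str], copies: Iterable[CopyHit],
                     flank: int = 50) -> list[StructuredCopy]:
    """TSD + TIR + superfamily for every accepted copy."""
    out = []
    for c in copies:
        fl = extract_flanks(genome, c, flank)
        tsd = detect_tsd(fl)
        tir = detect_tir(fl.element)
        out.append(StructuredCopy(c, tsd, tir, classify_superfamily(tsd, tir)))
    return out


# ---------------------------------------------------------------------------
# 80-80-80 family clustering


@dataclass
class FamilyCluster:
    members: list[str]
    representative: str


def _related_80_80_80(seq_a: str, seq_b: str, min_identity: float = 80.0,
                      min_len: int = 80, min_coverage: float = 0.8) -> bool:
    shorter = min(len(seq_a), len(seq_b))
    needed = max(min_len, int(round(min_coverage * shorter)))
    for b in (seq_b, align.revcomp(seq_b)):
        a = align.best_local_alignment(seq_a, b)
        if a.length >= needed and a.identity >= min_identity:
            return True
    return False


def cluster_families(consensi: Mapping[str, str], min_identity: float = 80.0,
                     min_len: int = 80,
                     min_coverage: float = 0.8) -> list[FamilyCluster]:
    """Single-linkage 80-80-80 clustering of consensus sequences.

    Two consensi are linked iff they share a local alignment with
    >= min_identity over >= min_coverage of the shorter sequence and
    >= min_len bp; families are the connected components. The representative
    is the longest member (ties: lexicographically smallest name). The
    partition is input-order invariant.
    """
    if not consensi:
        raise ParameterError("empty consensus set")
    names = sorted(consensi)
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if find(a) != find(b) and _related_80_80_80(
                    consensi[a], consensi[b], min_identity, min_len,
                    min_coverage):
                parent[find(b)] = find(a)

    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    clusters = []
    for members in groups.values():
        members.sort()
        # representative = longest member; ties go to the smallest name
        longest = max(len(consensi[n]) for n in members)
        rep = min(n for n in members if len(consensi[n]) == longest)
        clusters.append(FamilyCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative)
    return clusters


# ---------------------------------------------------------------------------
# autonomous Mutator mining


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _six_frame_hits(genome: Mapping[str, str], proteins: Mapping[str, str],
                    min_score: float) -> list[Interval]:
    """Genomic spans with translated similarity to any query protein."""
    aligner = _protein_aligner()
    spans: list[Interval] = []
    for contig, seq in genome.items():
        n = len(seq)
        frames = []
        for off in range(3):
            sub = seq[off:]
            sub = sub[: len(sub) // 3 * 3]
            frames.append((off, "+", str(Seq(sub).translate())))
        rc = align.revcomp(seq)
        for off in range(3):
            sub = rc[off:]
            sub = sub[: len(sub) // 3 * 3]
            frames.append((off, "-", str(Seq(sub).translate())))
        for off, strand, aa in frames:
            if not aa:
                continue
            for pname, prot in proteins.items():
                alignment = aligner.align(aa.replace("*", "X"), prot)
                if alignment.score < min_score:
                    continue
                best = alignment[0]
                a_start = int(best.aligned[0][0][0])
                a_end = int(best.aligned[0][-1][1])
                if strand == "+":
                    g_start, g_end = off + 3 * a_start, off + 3 * a_end
                else:
                    g_start = n - (off + 3 * a_end)
                    g_end = n - (off + 3 * a_start)
                spans.append(Interval(contig, g_start, g_end, strand))
    # merge overlapping hit spans per contig
    merged: list[Interval] = []
    for contig in sorted({s.contig for s in spans}):
        ivs = sorted([s for s in spans if s.contig == contig],
                     key=lambda iv: iv.start)
        cur = ivs[0]
        for iv in ivs[1:]:
            if iv.start <= cur.end:
                cur = Interval(contig, cur.start, max(cur.end, iv.end), cur.strand)
            else:
                merged.append(cur)
                cur = iv
        merged.append(cur)
    return merged


def _find_arm_pair(left: str, right: str, min_identity: float, min_arm: int):
    """Best inverted-repeat arm pair: one arm per flank, complementary
    orientation. Returns (left_start, right_end_from_right_start, arm, identity)
    in local flank coordinates, or None."""
    if not left or not right:
        return None
    # +1/-1 with a stiff gap (-4) keeps spurious maxima of a random 4-kb
    # flank comparison (~14) below a real arm's score; cheaper gaps let
    # chance alignments wander across diagonals and qualify. The score floor
    # (min_arm) means an accepted arm carries at least that much net match
    # signal, mirroring the significance floor a blast self-hit applies.
    a = align.best_local_alignment(left, align.revcomp(right), gap=-4)
    if a.length < min_arm or a.identity < min_identity or a.score < min_arm:
        return None
    # positions on revcomp(right) map back: r = len(right) - x
    right_end = len(right) - a.t_start
    return a.q_start, right_end, a.length, a.identity


def mine_autonomous(genome: Mapping[str, str], proteins: Mapping[str, str],
                    flank: int = 4000, min_protein_score: float = 100.0,
                    min_tir_identity: float = 50.0,
                    min_tir_arm: int = 20) -> list[AutonomousElement]:
    """Mine putative autonomous elements around transposase similarity.

    Translated local search of the protein queries against all six frames;
    each hit region is extended by ``flank`` on both sides and scanned for an
    inverted-repeat arm pair (one arm per flank, complementary orientation,
    identity >= 50%, arm >= 20 bp). Boundaries are the outermost arm
    coordinates; regions without an arm pair are reported as candidates
    without boundaries.
    """
    if not proteins:
        raise ParameterError("no protein queries given")
    out = []
    for hit in _six_frame_hits(genome, proteins, min_protein_score):
        seq = genome[hit.contig]
        w_start = max(0, hit.start - flank)
        w_end = min(len(seq), hit.end + flank)
        left = seq[w_start: hit.start]
        right = seq[hit.end: w_end]
        pair = _find_arm_pair(left, right, min_tir_identity, min_tir_arm)
        if pair is None:
            out.append(AutonomousElement(hit.contig, hit.start, hit.end,
                                         None, None, 0, 0.0))
        else:
            l_start, r_end, arm, ident = pair
            out.append(AutonomousElement(
                hit.contig, hit.start, hit.end,
                start=w_start + l_start, end=hit.end + r_end,
                tir_arm=arm, tir_identity=ident))
    return out


# ---------------------------------------------------------------------------
# MiM <-> autonomous linkage


@dataclass(frozen=True)
class MimLink:
    mim: str
    autonomous_index: int
    end: str  # "5p" or "3p"
    identity: float
    length: int


def link_mim_to_autonomous(mim_consensi: Mapping[str, str],
                           autonomous: Sequence[AutonomousElement],
                           genome: Mapping[str, str], end_len: int = 50,
                           min_identity: float = 80.0,
                           min_len: int = 30) -> tuple[list[MimLink], list[str]]:
    """Link MiM consensi to mined autonomous elements via their termini.

    Both ``end_len``-bp terminal segments of each MiM are locally aligned
    against each autonomous element (both strands); a link is reported when
    either end matches with identity >= 80% over >= 30 bp. Consensi shorter
    than ``end_len`` are flagged and skipped. Returns (links, flagged names).
    """
    links: list[MimLink] = []
    flagged: list[str] = []
    for name, seq in mim_consensi.items():
        if len(seq) < end_len:
            flagged.append(name)
            continue
        ends = {"5p": seq[:end_len], "3p": seq[-end_len:]}
        for idx, auto in enumerate(autonomous):
            s, e = auto.sequence_span
            target = genome[auto.contig][s:e]
            for label, endseq in ends.items():
                best = None
                for t in (target, align.revcomp(target)):
                    a = align.best_local_alignment(endseq, t)
                    if a.length >= min_len and a.identity >= min_identity:
                        if best is None or a.score > best.score:
                            best = a
                if best is not None:
                    links.append(MimLink(name, idx, label, best.identity,
                                         best.length))
    return links, flagged
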