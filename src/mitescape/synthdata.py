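"""Synthetic genomes with planted MITE copies and known ground truth.

The generator emulates the inputs of a genome-wide MITE survey at desk scale:
random contigs carrying gene models (exon/intron/UTR/CDS structure on both
strands), MITE families planted as full-length copies with
superfamily-specific target site duplications and controlled sequence
divergence, and Poisson read-count tables over MITE segments and whole genes
with controllable M/g expression ratios.

Insertions are modelled as point events on the base coordinate system: each
planted copy is written as TSD + element + TSD at its site, and all downstream
coordinates (other copies, gene features) shift accordingly, with features
that span an insertion point widening around it -- the situation a gene
annotation presents after a MITE lands in one of its features. Insertions are
non-nested, and sites keep a >=130 bp spacing so 50-nt flanks never touch a
neighbouring element. Copy termini (first/last 3 bp) are exempt from
divergence mutations: transposition-competent ends are the most conserved part
of a real element, and the full-length acceptance rules presume intact ends.

MiM-labelled families are planted inside generated (TA)n stretches (n >= 5)
with deliberately degenerate TIR arms, mirroring MITEs inserted in
microsatellites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import align, seqio
from .errors import CapacityError, ParameterError, UnknownReferenceError
from .seqio import GeneModel, Interval

BASES = np.array(list("ACGT"))

#: minimum spacing between insertion points on a contig (keeps flanks clean)
SITE_SPACING = 130

#: bases at each element end never mutated by divergence
PROTECTED_END = 3


@dataclass(frozen=True)
class FamilyBlueprint:
    """Recipe for one synthetic MITE family."""

    name: str
    superfamily: str  # Stowaway | Tourist | hAT-like | Mutator-like | MiM
    length: int
    tir_arm: int
    tir_identity: float = 100.0  # MiMs use a degraded arm (< 80%)


@dataclass(frozen=True)
class MiteFamily:
    """A named consensus with its structural annotation."""

    name: str
    superfamily: str
    consensus: str
    tir_arm: int


@dataclass(frozen=True)
class PlantedCopy:
    """Ground-truth record of one planted copy (final genome coordinates)."""

    copy_id: str
    family: str
    superfamily: str
    contig: str
    start: int
    end: int
    strand: str
    tsd: str
    realized_divergence: float
    context_truth: str | None = None


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic data set.

    Defaults follow the scale used throughout the test-bench: a 2-Mb genome in
    two contigs, eight families (two per superfamily lineage, lengths matching
    the mean element lengths observed in the carrot survey: Stowaway ~254 bp,
    Tourist ~319 bp, Mutator-like ~429 bp, hAT-like ~454 bp, one MiM family),
    25 copies per family, 10% divergence, 120 genes, and twenty RNA libraries
    of two million reads.
    """

    seed: int
    genome_length: int = 2_000_000
    n_contigs: int = 2
    families: Sequence[FamilyBlueprint] = ()
    copies_per_family: int = 25
    divergence: float = 0.10
    n_genes: int = 120
    exon_count_range: tuple[int, int] = (1, 4)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (80, 400)
    utr_len_range: tuple[int, int] = (40, 120)
    libraries: Sequence[tuple[str, int]] = tuple(
        (f"tissue_{i:02d}", 2_000_000) for i in range(1, 21))
    context_mix: Mapping[str, float] | None = None
    target_mg: float | Mapping[str, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 0.3):
            raise ParameterError("divergence must be in [0, 0.3]")
        if not self.families:
            self.families = default_families()
        planted = sum(b.length * self.copies_per_family for b in self.families)
        if self.genome_length <= planted:
            raise ParameterError("genome_length must exceed total planted bp")


def default_families() -> tuple[FamilyBlueprint, ...]:
    return (
        FamilyBlueprint("DcSto_like1", "Stowaway", 254, 12),
        FamilyBlueprint("DcSto_like2", "Stowaway", 240, 11),
        FamilyBlueprint("Krak_like1", "Tourist", 319, 14),
        FamilyBlueprint("Krak_like2", "Tourist", 300, 13),
        FamilyBlueprint("hAT_like1", "hAT-like", 454, 14),
        FamilyBlueprint("hAT_like2", "hAT-like", 430, 12),
        FamilyBlueprint("Mut_like1", "Mutator-like", 429, 30),
        FamilyBlueprint("MiM_1", "MiM", 400, 20, tir_identity=60.0),
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# families


def make_family(superfamily: str, length: int, tir_arm: int,
                seed: int | np.random.Generator, name: str | None = None,
                tir_identity: float = 100.0) -> MiteFamily:
    """Build a consensus whose trailing ``tir_arm`` bases are the reverse
    complement of its leading ones (degraded to ``tir_identity`` %).

    MITEs are short non-coding elements; lengths above 700 bp or below
    2*tir_arm+20 are rejected.
    """
    if length > 700:
        raise ParameterError("MITE consensi are <= 700 bp")
    if length < 2 * tir_arm + 20:
        raise ParameterError("length must be >= 2*tir_arm + 20")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arm = _random_seq(rng, tir_arm)
    interior = _random_seq(rng, length - 2 * tir_arm)
    trailing = list(align.revcomp(arm))
    n_degrade = round((1.0 - tir_identity / 100.0) * tir_arm)
    if n_degrade:
        for pos in rng.choice(tir_arm, size=n_degrade, replace=False):
            old = trailing[pos]
            trailing[pos] = rng.choice([b for b in "ACGT" if b != old])
    consensus = arm + interior + "".join(trailing)
    if name is None:
        name = f"{superfamily}_{seed if isinstance(seed, int) else 'fam'}"
    return MiteFamily(name, superfamily, consensus, tir_arm)


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, float]:
    """i.i.d. substitutions at the given rate, terminal bases protected."""
    if divergence == 0.0 or len(seq) <= 2 * PROTECTED_END:
        return seq, 0.0
    chars = list(seq)
    n_sub = 0
    hits = rng.random(len(chars)) < divergence
    for i in range(PROTECTED_END, len(chars) - PROTECTED_END):
        if hits[i]:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            n_sub += 1
    return "".join(chars), n_sub / len(chars)


# ---------------------------------------------------------------------------
# insertion machinery


@dataclass
class _Insertion:
    contig: str
    point: int  # base-coordinate insertion point
    prefix: str
    element: str
    suffix: str
    family: str
    superfamily: str
    strand: str
    tsd: str
    realized_divergence: float


def _make_insertion(rng: np.random.Generator, family: MiteFamily,
                    divergence: float, contig: str, point: int,
                    host_seq: str) -> _Insertion:
    element, realized = _mutate(rng, family.consensus, divergence)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        element = align.revcomp(element)
    sf = family.superfamily
    if sf == "MiM":
        run = int(rng.integers(5, 9))
        ta = "TA" * run
        return _Insertion(contig, point, ta, element, ta, family.name, sf,
                          strand, "TA", realized)
    if sf == "Stowaway":
        tsd = "TA"
    elif sf == "Tourist":
        tsd = str(rng.choice(["TAA", "TTA"]))
    else:
        # hAT / Mutator: duplicate the host k-mer at the target site; the
        # host copy right of the insertion point serves as the right TSD
        k = 8 if sf == "hAT-like" else int(rng.choice([9, 10]))
        host = host_seq[point: point + k]
        if len(host) == k and "N" not in host:
            return _Insertion(contig, point, host, element, "", family.name,
                              sf, strand, host, realized)
        tsd = _random_seq(rng, k)
    return _Insertion(contig, point, tsd, element, tsd, family.name, sf,
                      strand, tsd, realized)


def _apply_insertions(genome: Mapping[str, str],
                      insertions: Sequence[_Insertion],
                      ) -> tuple[dict[str, str], list[tuple[_Insertion, int, int]]]:
    """Emit the mutated genome; returns final (start, end) per insertion."""
    out_genome: dict[str, str] = {}
    placed: list[tuple[_Insertion, int, int]] = []
    by_contig: dict[str, list[_Insertion]] = {}
    for ins in insertions:
        by_contig.setdefault(ins.contig, []).append(ins)
    for contig, seq in genome.items():
        todo = sorted(by_contig.get(contig, []), key=lambda i: i.point)
        pieces = []
        cursor = 0
        offset = 0
        for ins in todo:
            pieces.append(seq[cursor: ins.point])
            elem_start = ins.point + offset + len(ins.prefix)
            placed.append((ins, elem_start, elem_start + len(ins.element)))
            pieces.append(ins.prefix + ins.element + ins.suffix)
            offset += len(ins.prefix) + len(ins.element) + len(ins.suffix)
            cursor = ins.point
        pieces.append(seq[cursor:])
        out_genome[contig] = "".join(pieces)
    return out_genome, placed


def _shift_interval(iv: Interval, points: Sequence[tuple[int, int]]) -> Interval:
    """Shift/widen one interval for insertions given as (point, length)."""
    ds = sum(m for p, m in points if p <= iv.start)
    de = sum(m for p, m in points if p < iv.end)
    return Interval(iv.contig, iv.start + ds, iv.end + de, iv.strand)


def _shift_genes(genes: Sequence[GeneModel],
                 insertions: Sequence[_Insertion]) -> list[GeneModel]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for ins in insertions:
        m = len(ins.prefix) + len(ins.element) + len(ins.suffix)
        by_contig.setdefault(ins.contig, []).append((ins.point, m))
    out = []
    for g in genes:
        pts = by_contig.get(g.contig, [])
        out.append(GeneModel(
            gene_id=g.gene_id, contig=g.contig, strand=g.strand,
            exons=[_shift_interval(iv, pts) for iv in g.exons],
            cds=[_shift_interval(iv, pts) for iv in g.cds],
            five_prime_utrs=[_shift_interval(iv, pts) for iv in g.five_prime_utrs],
            three_prime_utrs=[_shift_interval(iv, pts) for iv in g.three_prime_utrs]))
    return out


def plant_copies(genome: Mapping[str, str], family: MiteFamily, n: int,
                 divergence: float, seed: int | np.random.Generator,
                 exclude: Sequence[Interval] = (),
                 ) -> tuple[dict[str, str], list[PlantedCopy]]:
    """Plant ``n`` diverged copies of one family at uniform sites.

    Sites are sampled uniformly over the contigs, excluding ``exclude``
    intervals (e.g. previously planted elements) and keeping a spacing margin.
    Returns the mutated genome and the truth records (context_truth is None;
    use :func:`build_bundle` for gene-aware planting).
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if n == 0:
        return dict(genome), []
    taken: dict[str, list[int]] = {c: [] for c in genome}
    blocked: dict[str, list[Interval]] = {c: [] for c in genome}
    for iv in exclude:
        blocked.setdefault(iv.contig, []).append(iv)
    contigs = list(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    insertions: list[_Insertion] = []
    for _ in range(n):
        point = None
        for _try in range(500):
            c = contigs[rng.choice(len(contigs), p=lengths / lengths.sum())]
            p = int(rng.integers(60, len(genome[c]) - 60))
            if any(iv.start - SITE_SPACING < p < iv.end + SITE_SPACING
                   for iv in blocked[c]):
                continue
            if all(abs(p - q) >= SITE_SPACING for q in taken[c]):
                point, contig = p, c
                break
        if point is None:
            raise CapacityError("no remaining insertion space")
        taken[contig].append(point)
        insertions.append(_make_insertion(rng, family, divergence, contig,
                                          point, genome[contig]))
    new_genome, placed = _apply_insertions(genome, insertions)
    truth = [PlantedCopy(
        copy_id=f"{ins.family}_{i:04d}", family=ins.family,
        superfamily=ins.superfamily, contig=ins.contig, start=s, end=e,
        strand=ins.strand, tsd=ins.tsd,
        realized_divergence=ins.realized_divergence)
        for i, (ins, s, e) in enumerate(placed, start=1)]
    return new_genome, truth


# ---------------------------------------------------------------------------
# gene models


def make_gene_annotation(genome: Mapping[str, str], n_genes: int,
                         seed: int | np.random.Generator,
                         exon_count_range=(1, 4), exon_len_range=(120, 300),
                         intron_len_range=(80, 400), utr_len_range=(40, 120),
                         spacing: int = 2400) -> list[GeneModel]:
    """Non-overlapping genes on both strands with exon/intron/UTR structure.

    Genes are laid out left to right with at least ``spacing`` bp between
    spans, so 1-kb upstream/downstream windows of adjacent genes stay
    separable. The CDS is the exon union minus the terminal UTRs; on a
    minus-strand gene the 5'UTR sits on the higher-coordinate side.
    """
    if n_genes < 0:
        raise ParameterError("n_genes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    contigs = list(genome)
    genes: list[GeneModel] = []
    per_contig = [n_genes // len(contigs)] * len(contigs)
    for i in range(n_genes - sum(per_contig)):
        per_contig[i] += 1
    gene_no = 0
    for contig, quota in zip(contigs, per_contig):
        L = len(genome[contig])
        cursor = 1500
        for _ in range(quota):
            n_exons = int(rng.integers(exon_count_range[0],
                                       exon_count_range[1] + 1))
            exon_lens = [int(rng.integers(*exon_len_range))
                         for _ in range(n_exons)]
            intron_lens = [int(rng.integers(*intron_len_range))
                           for _ in range(n_exons - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            start = cursor + int(rng.integers(0, 400))
            if start + span + 1500 > L:
                raise CapacityError(
                    f"insufficient space for {n_genes} genes on {contig}")
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(_build_gene(f"gene_{gene_no:04d}", contig, strand,
                                     start, exon_lens, intron_lens,
                                     utr_len_range, rng))
            cursor = start + span + spacing
    return genes


def _build_gene(gene_id: str, contig: str, strand: str, start: int,
                exon_lens: Sequence[int], intron_lens: Sequence[int],
                utr_len_range, rng: np.random.Generator) -> GeneModel:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(Interval(contig, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    # left UTR inside first exon, right UTR inside last exon; keep >=20 bp of
    # CDS in between (single-exon genes share one budget)
    lo, hi = utr_len_range
    left_len = min(int(rng.integers(lo, hi)), len(exons[0]) - 20)
    right_len = min(int(rng.integers(lo, hi)), len(exons[-1]) - 20)
    if len(exons) == 1:
        budget = len(exons[0]) - 20
        left_len = min(left_len, budget // 2)
        right_len = min(right_len, budget - left_len)
    left_utr = Interval(contig, exons[0].start, exons[0].start + left_len, strand)
    right_utr = Interval(contig, exons[-1].end - right_len, exons[-1].end, strand)
    # CDS = exon union minus the two UTRs
    cds = []
    for i, e in enumerate(exons):
        s = max(e.start, left_utr.end if i == 0 else e.start)
        t = min(e.end, right_utr.start if i == len(exons) - 1 else e.end)
        if t > s:
            cds.append(Interval(contig, s, t, strand))
    if strand == "+":
        utr5, utr3 = [left_utr], [right_utr]
    else:
        utr5, utr3 = [right_utr], [left_utr]
    return GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                     exons=exons, cds=cds, five_prime_utrs=utr5,
                     three_prime_utrs=utr3)


# ---------------------------------------------------------------------------
# truth categorization (generator-side geometry; kept independent of
# genome_context so the two implementations can check each other)


def _truth_category(contig: str, start: int, end: int,
                    genes: Sequence[GeneModel], window: int = 1000) -> str:
    def overlaps(ivs):
        return any(iv.start < end and start < iv.end for iv in ivs)

    def contained(ivs):
        return any(iv.start <= start and end <= iv.end for iv in ivs)

    here = [g for g in genes if g.contig == contig]
    if overlaps([iv for g in here for iv in g.five_prime_utrs]):
        return "five_prime_utr"
    if overlaps([iv for g in here for iv in g.three_prime_utrs]):
        return "three_prime_utr"
    if overlaps([iv for g in here for iv in g.cds]):
        return "cds"
    if contained([iv for g in here for iv in g.introns]):
        return "intron"
    for g in here:
        gap = (g.start - end) if g.strand == "+" else (start - g.end)
        if 0 <= gap <= window:
            return "upstream"
    for g in here:
        gap = (start - g.end) if g.strand == "+" else (g.start - end)
        if 0 <= gap <= window:
            return "downstream"
    return "intergenic"


# ---------------------------------------------------------------------------
# read counts


def simulate_read_counts(copies: Sequence[PlantedCopy],
                         genes: Sequence[GeneModel],
                         libraries: Sequence[tuple[str, int]],
                         target_mg: float | Mapping[str, float] | None,
                         seed: int | np.random.Generator,
                         copy_gene: Mapping[str, str],
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Poisson count table over genes and MITE segments.

    Gene expression weights are lognormal; the expected MITE-segment count is
    set so that the expected normalized-RPK ratio M/g equals the requested
    target for each copy (scalar target, per-copy mapping, or None for a
    uniform draw in [0.2, 4)). Copies without a host gene get zero expected
    counts. Returns (counts table, nominal library sizes).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    gene_lens = {g.gene_id: g.end - g.start for g in genes}
    copy_lens = {c.copy_id: c.end - c.start for c in copies}
    if isinstance(target_mg, Mapping):
        for cid in target_mg:
            if cid not in copy_lens:
                raise UnknownReferenceError(f"unknown MITE copy id {cid!r}")
    for cid, gid in copy_gene.items():
        if cid not in copy_lens:
            raise UnknownReferenceError(f"unknown MITE copy id {cid!r}")
        if gid is not None and gid not in gene_lens:
            raise UnknownReferenceError(f"unknown gene id {gid!r}")

    def mg_of(cid: str) -> float:
        if target_mg is None:
            return float(rng.uniform(0.2, 4.0))
        if isinstance(target_mg, Mapping):
            return float(target_mg.get(cid, 0.0))
        return float(target_mg)

    targets = {c.copy_id: mg_of(c.copy_id) for c in copies}
    weights = {g.gene_id: float(rng.lognormal(0.0, 1.0)) for g in genes}
    wsum = sum(weights.values()) or 1.0
    rows = []
    lib_sizes = {}
    for lib, size in libraries:
        lib_sizes[lib] = int(size)
        gene_expect = {gid: size * 0.5 * w / wsum for gid, w in weights.items()}
        for gid in gene_lens:
            rows.append({"feature_id": gid, "feature_type": "gene",
                         "library": lib,
                         "count": int(rng.poisson(gene_expect[gid]))})
        for c in copies:
            gid = copy_gene.get(c.copy_id)
            if gid is None:
                lam = 0.0
            else:
                lam = (targets[c.copy_id] * gene_expect[gid]
                       * copy_lens[c.copy_id] / gene_lens[gid])
            rows.append({"feature_id": c.copy_id,
                         "feature_type": "mite_segment", "library": lib,
                         "count": int(rng.poisson(lam)) if lam > 0 else 0})
    counts = pd.DataFrame(rows, columns=["feature_id", "feature_type",
                                         "library", "count"])
    return counts, lib_sizes


# ---------------------------------------------------------------------------
# whole-bundle orchestration


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    genome: dict[str, str]
    families: dict[str, MiteFamily]
    copies: list[PlantedCopy]
    genes: list[GeneModel]
    counts: pd.DataFrame
    library_sizes: dict[str, int]
    copy_gene: dict[str, str | None]
    mg_targets: dict[str, float] = field(default_factory=dict)

    @property
    def consensus_library(self) -> dict[str, str]:
        return {f.name: f.consensus for f in self.families.values()}

    @property
    def feature_lengths(self) -> dict[str, int]:
        out = {g.gene_id: g.end - g.start for g in self.genes}
        out.update({c.copy_id: c.end - c.start for c in self.copies})
        return out


def _site_in_features(p: int, genes: Sequence[GeneModel], contig: str,
                      margin: int = 10) -> bool:
    for g in genes:
        if g.contig == contig and g.start - margin < p < g.end + margin:
            return True
    return False


def _targeted_point(rng: np.random.Generator, category: str,
                    genes: Sequence[GeneModel], genome: Mapping[str, str],
                    taken: Mapping[str, list[int]]) -> tuple[str, int] | None:
    """A base-coordinate insertion point whose copy will realise ``category``."""
    pool: list[tuple[str, int, int]] = []
    if category in ("five_prime_utr", "three_prime_utr", "cds", "intron"):
        for g in genes:
            if category == "five_prime_utr":
                ivs = g.five_prime_utrs
            elif category == "three_prime_utr":
                ivs = g.three_prime_utrs
            elif category == "cds":
                ivs = g.cds
            else:
                ivs = g.introns
            for iv in ivs:
                lo, hi = iv.start + 15, iv.end - 15
                if hi > lo:
                    pool.append((g.contig, lo, hi))
    elif category in ("upstream", "downstream"):
        for g in genes:
            left_side = (g.strand == "+") == (category == "upstream")
            if left_side:
                lo, hi = g.start - 900, g.start - 60
            else:
                lo, hi = g.end + 60, g.end + 900
            pool.append((g.contig, lo, hi))
    else:  # intergenic: keep >1.1 kb away from every gene span
        for contig, seq in genome.items():
            edges = sorted([(g.start, g.end) for g in genes
                            if g.contig == contig])
            prev = 60
            for s, e in edges + [(len(seq) - 60, len(seq) - 60)]:
                lo, hi = prev + 1100, s - 1100
                if hi > lo:
                    pool.append((contig, lo, hi))
                prev = e
    if not pool:
        return None
    for _ in range(500):
        contig, lo, hi = pool[int(rng.integers(0, len(pool)))]
        p = int(rng.integers(lo, hi))
        if p < 60 or p > len(genome[contig]) - 60:
            continue
        if category in ("upstream", "downstream", "intergenic") \
                and _site_in_features(p, genes, contig):
            continue
        if all(abs(p - q) >= SITE_SPACING for q in taken[contig]):
            return contig, p
    return None


def build_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate the full synthetic data set for one spec (deterministic in
    the seed)."""
    rng = np.random.default_rng(spec.seed)
    n_per = spec.genome_length // spec.n_contigs
    genome = {f"contig_{i + 1}": _random_seq(rng, n_per)
              for i in range(spec.n_contigs)}
    genes = make_gene_annotation(
        genome, spec.n_genes, rng, spec.exon_count_range, spec.exon_len_range,
        spec.intron_len_range, spec.utr_len_range)
    families = {}
    for bp in spec.families:
        families[bp.name] = make_family(bp.superfamily, bp.length, bp.tir_arm,
                                        rng, name=bp.name,
                                        tir_identity=bp.tir_identity)

    taken: dict[str, list[int]] = {c: [] for c in genome}
    insertions: list[_Insertion] = []
    categories_cycle = _category_schedule(spec)
    for fam in families.values():
        for k in range(spec.copies_per_family):
            category = categories_cycle[k % len(categories_cycle)] \
                if categories_cycle else None
            site = None
            if category is not None:
                site = _targeted_point(rng, category, genes, genome, taken)
            if site is None:
                site = _untargeted_point(rng, genes, genome, taken)
            if site is None:
                raise CapacityError("no remaining insertion space")
            contig, p = site
            taken[contig].append(p)
            insertions.append(_make_insertion(rng, fam, spec.divergence,
                                              contig, p, genome[contig]))

    final_genome, placed = _apply_insertions(genome, insertions)
    final_genes = _shift_genes(genes, insertions)
    counters: dict[str, int] = {}
    copies = []
    for ins, s, e in placed:
        counters[ins.family] = counters.get(ins.family, 0) + 1
        copies.append(PlantedCopy(
            copy_id=f"{ins.family}_{counters[ins.family]:04d}",
            family=ins.family, superfamily=ins.superfamily, contig=ins.contig,
            start=s, end=e, strand=ins.strand, tsd=ins.tsd,
            realized_divergence=ins.realized_divergence,
            context_truth=_truth_category(ins.contig, s, e, final_genes)))

    copy_gene = {c.copy_id: _truth_gene(c, final_genes) for c in copies}
    mg_targets = {}
    genic = [c for c in copies if copy_gene[c.copy_id] is not None]
    for c in genic:
        if spec.target_mg is None:
            mg_targets[c.copy_id] = float(rng.uniform(0.2, 4.0))
        elif isinstance(spec.target_mg, Mapping):
            mg_targets[c.copy_id] = float(spec.target_mg.get(c.copy_id, 0.0))
        else:
            mg_targets[c.copy_id] = float(spec.target_mg)
    counts, lib_sizes = simulate_read_counts(
        copies, final_genes, spec.libraries, mg_targets, rng, copy_gene)
    return SyntheticBundle(spec=spec, genome=final_genome, families=families,
                           copies=copies, genes=final_genes, counts=counts,
                           library_sizes=lib_sizes, copy_gene=copy_gene,
                           mg_targets=mg_targets)


def _category_schedule(spec: SyntheticSpec) -> list[str]:
    if spec.context_mix is None:
        return []
    schedule = []
    for cat, frac in spec.context_mix.items():
        schedule.extend([cat] * max(1, round(frac * spec.copies_per_family)))
    return schedule[: spec.copies_per_family]


def _untargeted_point(rng: np.random.Generator, genes: Sequence[GeneModel],
                      genome: Mapping[str, str],
                      taken: Mapping[str, list[int]]) -> tuple[str, int] | None:
    contigs = list(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    exonish = {c: [] for c in contigs}
    for g in genes:
        for iv in g.exons + g.five_prime_utrs + g.three_prime_utrs + g.cds:
            exonish[g.contig].append((iv.start, iv.end))
    for _ in range(500):
        c = contigs[int(rng.choice(len(contigs), p=lengths / lengths.sum()))]
        p = int(rng.integers(60, len(genome[c]) - 60))
        if any(s - 10 < p < e + 10 for s, e in exonish[c]):
            continue
        if all(abs(p - q) >= SITE_SPACING for q in taken[c]):
            return c, p
    return None


def _truth_gene(copy: PlantedCopy, genes: Sequence[GeneModel],
                window: int = 1000) -> str | None:
    if copy.context_truth in (None, "intergenic"):
        return None
    best = None
    for g in genes:
        if g.contig != copy.contig:
            continue
        dist = max(g.start - copy.end, copy.start - g.end, 0)
        if dist <= window and (best is None or dist < best[0]):
            best = (dist, g.gene_id)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# writers


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, family FASTA, truth TSV, gene GFF3 and count TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "families": out / "families.fasta",
        "truth": out / "truth.tsv",
        "genes": out / "genes.gff3",
        "counts": out / "counts.tsv",
        "library_sizes": out / "library_sizes.tsv",
    }
    seqio.write_fasta(bundle.genome, paths["genome"])
    seqio.write_fasta(bundle.consensus_library, paths["families"])
    truth = pd.DataFrame([{
        "copy_id": c.copy_id, "contig": c.contig, "start": c.start,
        "end": c.end, "strand": c.strand, "family": c.family,
        "superfamily": c.superfamily, "tsd": c.tsd,
        "realized_divergence": round(c.realized_divergence, 6),
        "category": c.context_truth or ""} for c in bundle.copies])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    seqio.write_gene_gff3(bundle.genes, paths["genes"])
    # MITE segments are keyed the way the annotation names copies
    # (family:contig:start-end) so external count tables join directly
    coord_id = {c.copy_id: f"{c.family}:{c.contig}:{c.start}-{c.end}"
                for c in bundle.copies}
    counts = bundle.counts.copy()
    counts["feature_id"] = [coord_id.get(f, f) for f in counts["feature_id"]]
    counts.to_csv(paths["counts"], sep="\t", index=False)
    pd.DataFrame([{"library": k, "size": v}
                  for k, v in bundle.library_sizes.items()]
                 ).to_csv(paths["library_sizes"], sep="\t", index=False)
    return paths
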