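"""Generator tests: planted truth must be exact and reproducible."""

import numpy as np
import pytest

from mitescape import align, seqio, synthdata
from mitescape.errors import ParameterError, UnknownReferenceError

from conftest import random_seq


# ---------------------------------------------------------------------------
# make_family


def test_make_family_has_perfect_tir():
    fam = synthdata.make_family("Stowaway", 254, 12, seed=1)
    assert len(fam.consensus) == 254
    assert fam.consensus[-12:] == align.revcomp(fam.consensus[:12])
    assert fam.superfamily == "Stowaway"


def test_make_family_deterministic():
    a = synthdata.make_family("hAT-like", 454, 14, seed=2)
    b = synthdata.make_family("hAT-like", 454, 14, seed=2)
    assert a.consensus == b.consensus


@pytest.mark.parametrize("length,arm", [(30, 20), (720, 10), (25, 3)])
def test_make_family_rejects_bad_geometry(length, arm):
    with pytest.raises(ParameterError):
        synthdata.make_family("Stowaway", length, arm, seed=1)


def test_make_family_degraded_tir():
    fam = synthdata.make_family("MiM", 400, 20, seed=3, tir_identity=60.0)
    lead = fam.consensus[:20]
    trail_rc = align.revcomp(fam.consensus[-20:])
    matches = sum(a == b for a, b in zip(lead, trail_rc))
    assert matches == 12  # 60% of 20


# ---------------------------------------------------------------------------
# plant_copies


def test_plant_zero_copies_is_identity():
    rng = np.random.default_rng(0)
    genome = {"c1": random_seq(rng, 10_000)}
    fam = synthdata.make_family("Stowaway", 254, 12, seed=1)
    new, truth = synthdata.plant_copies(genome, fam, 0, 0.0, seed=5)
    assert new == genome and truth == []


def test_planted_copies_are_exact_at_zero_divergence():
    rng = np.random.default_rng(1)
    genome = {"c1": random_seq(rng, 60_000)}
    fam = synthdata.make_family("Tourist", 300, 13, seed=2)
    new, truth = synthdata.plant_copies(genome, fam, 20, 0.0, seed=6)
    assert len(truth) == 20
    for c in truth:
        planted = new[c.contig][c.start:c.end]
        expect = fam.consensus if c.strand == "+" else align.revcomp(fam.consensus)
        assert planted == expect
        assert c.realized_divergence == 0.0


def test_tsd_flanks_conserved():
    rng = np.random.default_rng(2)
    genome = {"c1": random_seq(rng, 80_000)}
    for sf, arm in (("Stowaway", 12), ("Tourist", 13), ("hAT-like", 14),
                    ("Mutator-like", 30), ("MiM", 20)):
        fam = synthdata.make_family(sf, 320, arm, seed=3)
        genome, truth = synthdata.plant_copies(
            genome, fam, 4, 0.1, seed=7,
            exclude=[seqio.Interval("c1", t.start, t.end) for t in []])
        for c in truth:
            k = len(c.tsd)
            seq = genome[c.contig]
            assert seq[c.start - k:c.start] == c.tsd
            assert seq[c.end:c.end + k] == c.tsd


def test_realized_divergence_matches_request():
    # mean realized identity ~ 1 - divergence within a 3-sigma binomial bound
    rng = np.random.default_rng(3)
    genome = {"c1": random_seq(rng, 300_000)}
    fam = synthdata.make_family("Stowaway", 254, 12, seed=4)
    d = 0.10
    _, truth = synthdata.plant_copies(genome, fam, 50, d, seed=8)
    L = 254
    effective = d * (L - 2 * synthdata.PROTECTED_END) / L  # conserved termini
    mean = np.mean([c.realized_divergence for c in truth])
    sigma = np.sqrt(effective * (1 - effective) / (L * 50))
    assert abs(mean - effective) < 3 * sigma


def test_mim_planted_in_ta_stretch():
    rng = np.random.default_rng(4)
    genome = {"c1": random_seq(rng, 50_000)}
    fam = synthdata.make_family("MiM", 400, 20, seed=5, tir_identity=60.0)
    new, truth = synthdata.plant_copies(genome, fam, 5, 0.0, seed=9)
    for c in truth:
        seq = new[c.contig]
        assert seq[c.start - 10:c.start] == "TA" * 5
        assert seq[c.end:c.end + 10] == "TA" * 5


# ---------------------------------------------------------------------------
# gene annotation


def test_gene_annotation_structure():
    rng = np.random.default_rng(5)
    genome = {"c1": random_seq(rng, 200_000)}
    genes = synthdata.make_gene_annotation(genome, 10, seed=10)
    assert len(genes) == 10
    spans = sorted((g.start, g.end) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # non-overlapping
    for g in genes:
        g.validate()  # CDS within exon union
        assert g.exons and g.cds


def test_minus_strand_five_prime_utr_on_high_side():
    rng = np.random.default_rng(6)
    genome = {"c1": random_seq(rng, 400_000)}
    genes = synthdata.make_gene_annotation(genome, 30, seed=11)
    minus = [g for g in genes if g.strand == "-"]
    assert minus
    for g in minus:
        assert g.five_prime_utrs[0].end == g.end
        assert g.three_prime_utrs[0].start == g.start


def test_gff3_bytes_deterministic(tmp_path):
    rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
    genome = {"c1": random_seq(np.random.default_rng(0), 100_000)}
    a, b = tmp_path / "a.gff3", tmp_path / "b.gff3"
    seqio.write_gene_gff3(synthdata.make_gene_annotation(genome, 5, rng1), a)
    seqio.write_gene_gff3(synthdata.make_gene_annotation(genome, 5, rng2), b)
    assert a.read_bytes() == b.read_bytes()


def test_gene_annotation_round_trips_through_gff3(tmp_path):
    rng = np.random.default_rng(8)
    genome = {"c1": random_seq(rng, 150_000)}
    genes = synthdata.make_gene_annotation(genome, 8, seed=12)
    path = tmp_path / "genes.gff3"
    seqio.write_gene_gff3(genes, path)
    back = seqio.read_gff3(path)
    assert len(back) == len(genes)
    for orig, rt in zip(sorted(genes, key=lambda g: g.start),
                        sorted(back, key=lambda g: g.start)):
        assert (orig.start, orig.end, orig.strand) == (rt.start, rt.end, rt.strand)
        assert [(iv.start, iv.end) for iv in orig.exons] \
            == [(iv.start, iv.end) for iv in rt.exons]


# ---------------------------------------------------------------------------
# read counts


def _one_gene_setup():
    gene = seqio.GeneModel(
        gene_id="g1", contig="c1", strand="+",
        exons=[seqio.Interval("c1", 1000, 3000)],
        cds=[seqio.Interval("c1", 1100, 2900)])
    copy = synthdata.PlantedCopy(
        copy_id="m1", family="famA", superfamily="Stowaway", contig="c1",
        start=1500, end=1800, strand="+", tsd="TA", realized_divergence=0.0,
        context_truth="cds")
    return gene, copy


def test_simulated_counts_recover_target_mg():
    gene, copy = _one_gene_setup()
    counts, sizes = synthdata.simulate_read_counts(
        [copy], [gene], [("big", 4_000_000)], target_mg=2.5, seed=13,
        copy_gene={"m1": "g1"})
    c = counts.set_index("feature_id")["count"]
    est = (c["m1"] / 300) / (c["g1"] / 2000)
    assert abs(est - 2.5) / 2.5 < 0.10


def test_target_mg_zero_means_zero_reads():
    gene, copy = _one_gene_setup()
    counts, _ = synthdata.simulate_read_counts(
        [copy], [gene], [("l", 1_000_000)], target_mg=0.0, seed=14,
        copy_gene={"m1": "g1"})
    assert counts.set_index("feature_id")["count"]["m1"] == 0


def test_library_size_cancels_in_mg():
    gene, copy = _one_gene_setup()
    counts, sizes = synthdata.simulate_read_counts(
        [copy], [gene], [("s", 2_000_000), ("d", 4_000_000)], target_mg=2.0,
        seed=15, copy_gene={"m1": "g1"})
    ests = []
    for lib in ("s", "d"):
        sub = counts[counts["library"] == lib].set_index("feature_id")["count"]
        ests.append((sub["m1"] / 300) / (sub["g1"] / 2000))
    assert abs(ests[0] - ests[1]) / ests[0] < 0.15  # same expectation


def test_unknown_ids_rejected():
    gene, copy = _one_gene_setup()
    with pytest.raises(UnknownReferenceError):
        synthdata.simulate_read_counts([copy], [gene], [("l", 1000)],
                                       target_mg={"ghost": 1.0}, seed=1,
                                       copy_gene={"m1": "g1"})
    with pytest.raises(UnknownReferenceError):
        synthdata.simulate_read_counts([copy], [gene], [("l", 1000)],
                                       target_mg=1.0, seed=1,
                                       copy_gene={"m1": "nogene"})


# ---------------------------------------------------------------------------
# bundle-level invariants


def test_bundle_is_seed_deterministic(tmp_path, clean_bundle):
    again = synthdata.build_bundle(clean_bundle.spec)
    assert again.genome == clean_bundle.genome
    assert again.copies == clean_bundle.copies
    d1, d2 = tmp_path / "one", tmp_path / "two"
    synthdata.write_bundle(clean_bundle, d1)
    synthdata.write_bundle(again, d2)
    for name in ("genome.fasta", "truth.tsv", "genes.gff3", "counts.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_bundle_truth_tsds_present_in_genome(small_bundle):
    for c in small_bundle.copies:
        k = len(c.tsd)
        seq = small_bundle.genome[c.contig]
        assert seq[c.start - k:c.start] == c.tsd
        assert seq[c.end:c.end + k] == c.tsd


def test_divergence_out_of_range_rejected():
    with pytest.raises(ParameterError):
        synthdata.SyntheticSpec(seed=1, divergence=0.4)
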