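"""Structural calls: TSD/TIR detection, superfamily mapping, 80-80-80
clustering, autonomous-element mining and MiM linkage."""

import numpy as np
import pytest

from mitescape import align, element_structure as es
from mitescape.errors import ParameterError

from conftest import mutate_evenly, random_seq


# ---------------------------------------------------------------------------
# detect_tsd


def _flanks(left, right, element="ACGT" * 30):
    return es.FlankPair(left_flank=left, right_flank=right, element=element)


def test_tsd_ta_dinucleotide():
    call = es.detect_tsd(_flanks("CCCCGCTA", "TAGCCCCC"))
    assert (call.tsd, call.k, call.exact) == ("TA", 2, True)


def test_tsd_eight_mer():
    call = es.detect_tsd(_flanks("CCCCACGTTGCA", "ACGTTGCACCCC"))
    assert (call.tsd, call.k, call.exact) == ("ACGTTGCA", 8, True)


def test_tsd_longest_k_wins():
    tsd = "GATCCATGGA"  # 10-mer; its 2-/3-suffixes also match trivially
    call = es.detect_tsd(_flanks("CC" + tsd, tsd + "CC"))
    assert (call.tsd, call.k) == (tsd, 10)


def test_tsd_one_mismatch_tolerated_only_for_long():
    left, right = "CCCCACGTTGCA", "ACGTTGGACCCC"  # 8-mer with 1 mismatch
    call = es.detect_tsd(_flanks(left, right))
    assert (call.k, call.exact) == (8, False)
    # 3-mers must be exact: TAA vs TAC is no call
    call = es.detect_tsd(_flanks("GGGCGCTAA", "TACGCGGGG"))
    assert call.k == 0


def test_tsd_ta_stretch_flag():
    call = es.detect_tsd(_flanks("GGGTATATA", "TATATAGGG"))
    assert call.ta_stretch
    call = es.detect_tsd(_flanks("GGGGCCGCA", "GCACCGGGG"))
    assert not call.ta_stretch


def test_tsd_clipped_flanks_no_call():
    call = es.detect_tsd(_flanks("A", "G"))
    assert call.k == 0 and call.tsd == ""


# ---------------------------------------------------------------------------
# detect_tir


def test_tir_perfect_eight_bp_arm():
    element = "CACTACAA" + "G" * 100 + "TTGTAGTG"
    call = es.detect_tir(element)
    assert call.arm == 8 and call.identity == 100.0


def test_tir_identity_with_one_mismatch():
    rng = np.random.default_rng(0)
    arm = random_seq(rng, 14)
    trail = list(align.revcomp(arm))
    trail[7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[trail[7]]
    interior = random_seq(rng, 200)
    call = es.detect_tir(arm + interior + "".join(trail), max_arm=14)
    assert call.arm == 14
    assert call.identity == pytest.approx(100 * 13 / 14, abs=0.01)


def test_tir_random_elements_rarely_reach_threshold():
    # empirical null: best arm identity of random 300-mers stays below the
    # 80% recognition threshold in the overwhelming majority of draws
    rng = np.random.default_rng(1)
    recognized = sum(
        es.detect_tir(random_seq(rng, 300)).recognized for _ in range(200))
    assert recognized <= 2


def test_tir_too_short_no_call():
    assert es.detect_tir("ACGTACGTACGTACG").arm == 0  # 15 < 16


# ---------------------------------------------------------------------------
# classify_superfamily


def _tsd(tsd, k, ta=False):
    return es.TsdCall(tsd, k, True, ta)


def _tir(identity, arm=14):
    return es.TirCall(arm, identity)


@pytest.mark.parametrize("tsd,expected", [
    (_tsd("TA", 2), "Stowaway"),
    (_tsd("TAA", 3), "Tourist"),
    (_tsd("TTA", 3), "Tourist"),
    (_tsd("ACGTTGCA", 8), "hAT-like"),
    (_tsd("ACGTTGCAA", 9), "Mutator-like"),
    (_tsd("ACGTTGCAAT", 10), "Mutator-like"),
    (_tsd("", 0), "Unclassified"),
])
def test_superfamily_mapping(tsd, expected):
    assert es.classify_superfamily(tsd, _tir(95.0)) == expected


def test_mim_requires_ta_stretch_and_weak_tir():
    assert es.classify_superfamily(_tsd("TA", 2, ta=True), _tir(60.0)) == "MiM"
    # strong TIR in a TA stretch is still a Stowaway
    assert es.classify_superfamily(_tsd("TA", 2, ta=True), _tir(95.0)) \
        == "Stowaway"
    assert es.GROUP_OF["MiM"] == "Mutator-like"


# ---------------------------------------------------------------------------
# cluster_families


def _brute_force_clusters(consensi):
    """Oracle: pairwise relation + connected components via networkx."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(consensi)
    names = list(consensi)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if es._related_80_80_80(consensi[a], consensi[b]):
                g.add_edge(a, b)
    return sorted(sorted(c) for c in nx.connected_components(g))


def test_identical_consensi_cluster_together():
    rng = np.random.default_rng(2)
    seq = random_seq(rng, 200)
    clusters = es.cluster_families({"a": seq, "b": seq})
    assert len(clusters) == 1 and clusters[0].members == ["a", "b"]


def test_single_linkage_chains_transitively():
    rng = np.random.default_rng(3)
    a = random_seq(rng, 300)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    # b: mismatches at i % 7 == 3 (~14%); c: additionally at i % 7 == 5,
    # so a~b and b~c sit above 80% while a~c (~71%) falls below
    b = "".join(flip[x] if 10 <= i < 290 and i % 7 == 3 else x
                for i, x in enumerate(a))
    c = "".join(flip[x] if 10 <= i < 290 and i % 7 == 5 else x
                for i, x in enumerate(b))
    consensi = {"A": a, "B": b, "C": c}
    ident_ac = 100 * sum(x == y for x, y in zip(a, c)) / 300
    assert ident_ac < 80
    clusters = es.cluster_families(consensi)
    assert len(clusters) == 1 and clusters[0].members == ["A", "B", "C"]
    assert [c.members for c in clusters] == _brute_force_clusters(consensi)


def test_dissimilar_pair_stays_apart():
    rng = np.random.default_rng(4)
    a, b = random_seq(rng, 250), random_seq(rng, 250)
    clusters = es.cluster_families({"a": a, "b": b})
    assert len(clusters) == 2


def test_clustering_is_order_invariant_and_idempotent():
    rng = np.random.default_rng(5)
    a = random_seq(rng, 300)
    consensi = {"x": a, "y": mutate_evenly(a, 0.9), "z": random_seq(rng, 280),
                "w": random_seq(rng, 150)}
    forward = es.cluster_families(consensi)
    shuffled = es.cluster_families(dict(reversed(list(consensi.items()))))
    assert [c.members for c in forward] == [c.members for c in shuffled]
    # idempotence: clustering the representatives changes nothing
    reps = {c.representative: consensi[c.representative] for c in forward}
    again = es.cluster_families(reps)
    assert sorted(c.representative for c in again) \
        == sorted(c.representative for c in forward)


def test_representative_is_longest_member():
    rng = np.random.default_rng(6)
    a = random_seq(rng, 300)
    longer = a + random_seq(rng, 30)
    clusters = es.cluster_families({"short": a, "long": longer})
    assert clusters[0].representative == "long"


def test_empty_consensus_set_rejected():
    with pytest.raises(ParameterError):
        es.cluster_families({})


# ---------------------------------------------------------------------------
# autonomous mining

_AA = "ARNDCQEGHILKMFPSTWYV"
_CODON = {"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
          "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
          "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
          "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT"}


def _transposase_plant(rng, arm_identity=1.0, with_arms=True):
    """Transposase ORF with 25-bp inverted-repeat arms ~3 kb away on each
    side. Sentinel triplets around the arms mismatch under the flank-vs-flank
    comparison, so the best alignment is exactly the planted arm pair."""
    protein = "".join(rng.choice(list(_AA)) for _ in range(120))
    orf = "".join(_CODON[a] for a in protein)
    arm = random_seq(rng, 25)
    right_arm = align.revcomp(mutate_evenly(arm, arm_identity, anchor=2)) \
        if with_arms else random_seq(rng, 25)
    left_arm = arm if with_arms else random_seq(rng, 25)
    pieces = [random_seq(rng, 1997), "AAA", left_arm, "CCC",
              random_seq(rng, 2969), orf, random_seq(rng, 2969), "CCC",
              right_arm, "AAA", random_seq(rng, 1997)]
    genome_seq = "".join(pieces)
    left_arm_start = 2000
    right_arm_end = 2000 + 25 + 3 + 2969 + len(orf) + 2969 + 3 + 25
    return {"c1": genome_seq}, {"tp": protein}, left_arm_start, right_arm_end


def test_autonomous_boundaries_exact_on_perfect_arms():
    rng = np.random.default_rng(7)
    genome, proteins, left, right = _transposase_plant(rng)
    found = es.mine_autonomous(genome, proteins)
    assert len(found) == 1
    el = found[0]
    assert el.has_boundaries
    assert (el.start, el.end) == (left, right)
    assert el.tir_identity == 100.0 and el.tir_arm == 25


def test_autonomous_low_identity_arms_discarded():
    rng = np.random.default_rng(8)
    genome, proteins, *_ = _transposase_plant(rng, arm_identity=0.4)
    found = es.mine_autonomous(genome, proteins)
    assert len(found) == 1
    assert not found[0].has_boundaries


def test_autonomous_no_arms_reported_as_candidate():
    rng = np.random.default_rng(9)
    genome, proteins, *_ = _transposase_plant(rng, with_arms=False)
    found = es.mine_autonomous(genome, proteins)
    assert len(found) == 1 and not found[0].has_boundaries


def test_autonomous_requires_protein_queries():
    with pytest.raises(ParameterError):
        es.mine_autonomous({"c": "ACGT" * 100}, {})


# ---------------------------------------------------------------------------
# MiM linkage


def test_mim_links_when_ends_copied_from_element():
    rng = np.random.default_rng(10)
    genome, proteins, left, right = _transposase_plant(rng)
    autos = es.mine_autonomous(genome, proteins)
    elem = genome["c1"][autos[0].start:autos[0].end]
    mim = elem[:50] + random_seq(rng, 200) + elem[-50:]
    links, flagged = es.link_mim_to_autonomous({"mim1": mim}, autos, genome)
    assert not flagged
    assert {l.end for l in links} == {"5p", "3p"}


def test_mim_random_ends_do_not_link():
    rng = np.random.default_rng(11)
    genome, proteins, *_ = _transposase_plant(rng)
    autos = es.mine_autonomous(genome, proteins)
    # empirical null: shuffled/random termini never reach 80% over 30 bp
    for trial in range(10):
        mim = random_seq(rng, 300)
        links, _ = es.link_mim_to_autonomous({"m": mim}, autos, genome)
        assert links == []


def test_mim_shorter_than_end_length_flagged():
    rng = np.random.default_rng(12)
    genome, proteins, *_ = _transposase_plant(rng)
    autos = es.mine_autonomous(genome, proteins)
    links, flagged = es.link_mim_to_autonomous({"tiny": "ACGT" * 10}, autos,
                                               genome)
    assert flagged == ["tiny"] and links == []


# ---------------------------------------------------------------------------
# end-to-end structural truth on the shared bundle


def test_planted_structure_fully_recovered(small_bundle):
    b = small_bundle
    for truth in b.copies:
        copy = type("C", (), {"contig": truth.contig, "start": truth.start,
                              "end": truth.end})()
        flanks = es.extract_flanks(b.genome, copy)
        tsd = es.detect_tsd(flanks)
        tir = es.detect_tir(flanks.element)
        assert es.classify_superfamily(tsd, tir) == truth.superfamily
        if truth.superfamily != "MiM":
            assert tsd.tsd == truth.tsd
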