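"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitescape import synthdata

BASES = np.array(list("ACGT"))
_FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate_evenly(seq: str, identity: float, anchor: int = 10) -> str:
    """Copy of ``seq`` at the requested identity with mismatches spread evenly
    and ``anchor`` clean bases at both ends, so a local aligner keeps the full
    region (no end trimming)."""
    n = len(seq)
    n_mut = round((1.0 - identity) * n)
    out = list(seq)
    if n_mut:
        pos = np.unique(np.round(
            np.linspace(anchor, n - anchor - 1, n_mut)).astype(int))
        for p in pos:
            out[p] = _FLIP[out[p]]
    return "".join(out)


def mutate_iid(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Copy of ``seq`` with i.i.d. substitutions at the given rate (the
    realistic divergence model; mismatch runs stay exponential, unlike
    :func:`mutate_evenly`)."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[i] = _FLIP[out[i]]
    return "".join(out)


def make_partial_pair(seed: int, frac: float, ident: float, L: int = 300):
    """Sequence pair whose best local alignment is a region of ``frac`` of the
    length at ``ident`` identity (clean anchors, so no end trimming)."""
    rng = np.random.default_rng(seed)
    a = random_seq(rng, L)
    reg_len = round(frac * L)
    region = mutate_evenly(a[:reg_len], ident)
    b = region + random_seq(rng, L - reg_len)
    return a, b


# ---------------------------------------------------------------------------
# independent exhaustive local-alignment oracle (row-major DP, separate code
# path from mitescape.align, which fills column by column)


def oracle_sw_matrix(query: str, target: str, match: int = 1,
                     mismatch: int = -1, gap: int = -2,
                     blocked: np.ndarray | None = None) -> np.ndarray:
    code = {c: i for i, c in enumerate("ACGT")}
    q = np.array([code.get(c, 4) for c in query], dtype=np.int32)
    t = np.array([code.get(c, 4) for c in target], dtype=np.int32)
    m, n = len(q), len(t)
    if blocked is None:
        blocked = np.zeros(n, dtype=bool)
    ok = (t != 4) & ~blocked
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    ramp = np.arange(n, dtype=np.int32) * gap
    for i in range(1, m + 1):
        s = np.where(ok & (t == q[i - 1]) & (q[i - 1] != 4), match, mismatch)
        E = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap)
        E = np.maximum(E, 0)
        row = np.maximum.accumulate(E - ramp) + ramp
        row[blocked] = 0
        H[i, 1:] = row
    return H


def oracle_traceback(H, query, target, i, j, match=1, mismatch=-1, gap=-2):
    """(score, q_start, q_end, t_start, t_end, matches, length)."""
    score = int(H[i, j])
    qe, te = i, j
    matches = length = 0
    while H[i, j] > 0:
        hit = (query[i - 1] == target[j - 1]
               and query[i - 1] in "ACGT")
        if H[i, j] == H[i - 1, j - 1] + (match if hit else mismatch):
            matches += hit
            length += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i, j - 1] + gap:
            length += 1
            j -= 1
        else:
            length += 1
            i -= 1
    return score, i, qe, j, te, matches, length


def oracle_extract(query: str, target: str, min_identity: float, min_len: int,
                   match: int = 1, mismatch: int = -1, gap: int = -2):
    """Waterman-Eggert extraction mirroring the documented hit semantics."""
    import math
    p = min_identity / 100.0
    floor = max(1, math.floor(min_len * (p * match + (1 - p) * mismatch)))
    blocked = np.zeros(len(target), dtype=bool)
    out = []
    while True:
        H = oracle_sw_matrix(query, target, match, mismatch, gap, blocked)
        i, j = np.unravel_index(int(np.argmax(H)), H.shape)
        if H[i, j] < floor:
            break
        aln = oracle_traceback(H, query, target, int(i), int(j),
                               match, mismatch, gap)
        score, qs, qe, ts, te, matches, length = aln
        blocked[ts:te] = True
        if length >= min_len and 100.0 * matches / length >= min_identity:
            out.append(aln)
    out.sort(key=lambda a: (a[3], a[4]))
    return out


# ---------------------------------------------------------------------------
# shared synthetic bundles (session-scoped: several modules test against them)


@pytest.fixture(scope="session")
def small_bundle() -> synthdata.SyntheticBundle:
    """400-kb genome, 8 families x 5 copies, mixed genomic contexts."""
    spec = synthdata.SyntheticSpec(
        seed=11, genome_length=400_000, n_contigs=2, copies_per_family=5,
        divergence=0.05, n_genes=40, target_mg=2.5,
        context_mix={"five_prime_utr": 0.2, "intron": 0.2, "upstream": 0.2,
                     "downstream": 0.2, "intergenic": 0.2},
        libraries=(("lib_a", 2_000_000), ("lib_b", 3_000_000)))
    return synthdata.build_bundle(spec)


@pytest.fixture(scope="session")
def clean_bundle() -> synthdata.SyntheticBundle:
    """Zero-divergence bundle: planted copies match their consensus exactly."""
    spec = synthdata.SyntheticSpec(
        seed=7, genome_length=300_000, n_contigs=1, copies_per_family=4,
        divergence=0.0, n_genes=20,
        libraries=(("lib_a", 1_000_000),))
    return synthdata.build_bundle(spec)
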