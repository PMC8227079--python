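"""Local sequence alignment engine.

A small Smith--Waterman kernel (linear gap penalty) plus k-mer seeding, used by
every stage that needs nucleotide-level local alignment: genome scanning for
MITE copies, 80-80-80 family clustering, read-to-copy matching, cross-species
family comparison and inverted-repeat arm detection.

Scoring defaults to match +1 / mismatch -1 / gap -2. Identity is
matches / alignment columns (gap columns included). Coordinates returned are
0-based half-open on both sequences.

The DP is vectorised over the query axis with a max-scan along each subject
column, so the kernel stays pure numpy; subject windows are kept small by
k-mer seeding when scanning whole contigs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: code assigned to N / any non-ACGT symbol; never matches anything, itself included
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment; spans are 0-based half-open."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    length: int  # alignment columns, gap columns included

    @property
    def identity(self) -> float:
        """Percent identity over the alignment."""
        return 100.0 * self.matches / self.length if self.length else 0.0


try:  # JIT kernel; the numpy scan below is the fallback and reference
    from numba import njit

    @njit(cache=True)
    def _sw_fill_numba(q, t, match, mismatch, gap, blocked):  # pragma: no cover
        m, n = len(q), len(t)
        H = np.zeros((m + 1, n + 1), dtype=np.int32)
        for j in range(1, n + 1):
            if blocked[j - 1]:
                continue
            tj = t[j - 1]
            for i in range(1, m + 1):
                qi = q[i - 1]
                s = match if (qi == tj and qi != 4) else mismatch
                best = H[i - 1, j - 1] + s
                up = H[i - 1, j] + gap
                left = H[i, j - 1] + gap
                if up > best:
                    best = up
                if left > best:
                    best = left
                if best < 0:
                    best = 0
                H[i, j] = best
        return H

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def sw_matrix(q: np.ndarray, t: np.ndarray, match: int = 1, mismatch: int = -1,
              gap: int = -2, blocked: np.ndarray | None = None) -> np.ndarray:
    """Full Smith--Waterman score matrix, shape (len(q)+1, len(t)+1).

    Linear gap penalty. Subject positions flagged in ``blocked`` contribute
    zero columns, so no alignment can cross them (Waterman-Eggert style
    masking for sub-optimal alignment extraction). The column recurrence's
    vertical dependency is resolved with a prefix-max scan
    (R[i] = max(E[i], R[i-1]+gap)), keeping the inner loop in numpy; a
    JIT-compiled fill is used when available.
    """
    m, n = len(q), len(t)
    if blocked is None:
        blocked = np.zeros(n, dtype=np.bool_)
    if _HAVE_NUMBA and m and n:
        return _sw_fill_numba(q.astype(np.int8), t.astype(np.int8),
                              match, mismatch, gap,
                              blocked.astype(np.bool_))
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    if m == 0 or n == 0:
        return H
    qcol = q.astype(np.int32)
    valid = qcol != N_CODE
    ramp = np.arange(m, dtype=np.int32) * gap
    for j in range(1, n + 1):
        if blocked[j - 1]:
            continue
        tj = t[j - 1]
        s = np.where(valid & (qcol == tj) & (tj != N_CODE), match, mismatch)
        prev = H[:, j - 1]
        E = np.maximum(prev[:-1] + s, prev[1:] + gap)
        np.maximum(E, 0, out=E)
        # vertical gap scan: R[i] = max(E[i], R[i-1] + gap)
        R = np.maximum.accumulate(E - ramp) + ramp
        H[1:, j] = R
    return H


def _traceback(H: np.ndarray, q: np.ndarray, t: np.ndarray, i: int, j: int,
               match: int, mismatch: int, gap: int) -> LocalAlignment:
    """Walk back from cell (i, j) until a zero cell; diag > left > up preference."""
    score = int(H[i, j])
    q_end, t_end = i, j
    matches = 0
    length = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        qi, tj = q[i - 1], t[j - 1]
        hit = qi == tj and qi != N_CODE
        s = match if hit else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(hit)
            length += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            length += 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            length += 1
            i -= 1
        else:  # pragma: no cover - would indicate a kernel bug
            raise AssertionError("inconsistent traceback")
    return LocalAlignment(score, i, q_end, j, t_end, matches, length)


def best_local_alignment(query: str, target: str, match: int = 1,
                         mismatch: int = -1, gap: int = -2) -> LocalAlignment:
    """Single best local alignment between two strings."""
    q, t = encode(query), encode(target)
    H = sw_matrix(q, t, match, mismatch, gap)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    if H[i, j] == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    return _traceback(H, q, t, int(i), int(j), match, mismatch, gap)


def score_floor(min_identity: float, min_len: int, match: int = 1,
                mismatch: int = -1) -> int:
    """Lowest SW score an alignment meeting the thresholds can have.

    An ungapped alignment of length L at identity p scores
    L*(p*match + (1-p)*mismatch); gaps only lower the score.
    """
    p = min_identity / 100.0
    return max(1, math.floor(min_len * (p * match + (1 - p) * mismatch)))


def extract_local_alignments(query: str, target: str, min_identity: float,
                             min_len: int, match: int = 1, mismatch: int = -1,
                             gap: int = -2) -> list[LocalAlignment]:
    """All maximal local alignments above the identity/length thresholds.

    Semantics (Waterman-Eggert style): the best alignment is reported, its
    subject span is masked out, and the matrix is recomputed; this repeats
    until the best score falls below the floor implied by the thresholds. The
    identity/length filter is applied to the extracted set afterwards. Ties
    are broken by row-major argmax order, which is deterministic.
    """
    if not query:
        raise ParameterError("empty query sequence")
    q, t = encode(query), encode(target)
    blocked = np.zeros(len(t), dtype=np.bool_)
    floor = score_floor(min_identity, min_len, match, mismatch)
    out: list[LocalAlignment] = []
    while True:
        H = sw_matrix(q, t, match, mismatch, gap, blocked)
        i, j = np.unravel_index(int(np.argmax(H)), H.shape)
        if H[i, j] < floor:
            break
        aln = _traceback(H, q, t, int(i), int(j), match, mismatch, gap)
        blocked[aln.t_start : aln.t_end] = True
        out.append(aln)
    kept = [a for a in out
            if a.identity >= min_identity and a.length >= min_len]
    kept.sort(key=lambda a: (a.t_start, a.t_end))
    return kept


def seed_windows(query: str, target: str, k: int = 11,
                 margin: int | None = None) -> list[tuple[int, int]]:
    """Subject windows likely to contain local alignments of ``query``.

    Exact k-mer matches between query and subject are clustered; clusters
    separated by more than len(query)+50 are split. Each window is padded by
    ``margin`` (default len(query)) and clipped to the subject.
    """
    m, n = len(query), len(target)
    if m < k or n < k:
        return [(0, n)] if n else []
    if margin is None:
        margin = m
    qk = _kmer_codes(encode(query), k)
    tk = _kmer_codes(encode(target), k)
    order = np.argsort(tk, kind="stable")
    tsorted = tk[order]
    positions: list[np.ndarray] = []
    for code in np.unique(qk[qk >= 0]):
        lo = np.searchsorted(tsorted, code, "left")
        hi = np.searchsorted(tsorted, code, "right")
        if hi > lo:
            positions.append(order[lo:hi])
    if not positions:
        return []
    pos = np.unique(np.concatenate(positions))
    gaps = np.diff(pos)
    breaks = np.nonzero(gaps > m + 50)[0]
    windows = []
    start_idx = 0
    for b in list(breaks) + [len(pos) - 1]:
        first, last = int(pos[start_idx]), int(pos[b])
        windows.append((max(0, first - margin), min(n, last + k + margin)))
        start_idx = b + 1
    # merge touching windows
    merged = [windows[0]]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the k-mer contains an N."""
    n = len(codes) - k + 1
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for i in range(k):
        window = c[i : i + n]
        vals = vals * 4 + np.where(window == N_CODE, 0, window)
        bad |= window == N_CODE
    vals[bad] = -1
    return vals
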