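"""Pairwise nucleotide alignment kernels.

Two alignments are needed by the pipeline: a local Smith–Waterman used for
V/J segment assignment and junction-boundary refinement (scoring defaults
match +5 / mismatch -4, linear gap -8), and an end-gap-free global alignment
used only to count identical positions for the percent-identity rule. Both
are numba-compiled dynamic programs; tie-breaking is fixed so outputs are
bit-reproducible:

* within a DP cell, predecessor preference is diagonal > gap-in-reference >
  gap-in-query;
* among equal-scoring local alignments, prefer the smaller reference start,
  then the smaller query start, then the shorter alignment, then the
  smaller end coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["AlignmentResult", "smith_waterman", "global_matches", "revcomp"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment: score, half-open query/ref intervals and operations.

    ``ops`` is a CIGAR-like list of ``(op, length)`` with op ``"M"``
    (aligned pair), ``"I"`` (query base against a gap in the reference) or
    ``"D"`` (reference base against a gap in the query).
    """

    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ops: tuple[tuple[str, int], ...]

    @property
    def is_empty(self) -> bool:
        return self.score <= 0

    def ref_to_query(self, ref_pos: int) -> int | None:
        """Map a reference coordinate onto the query through the alignment.

        Returns the query position aligned to ``ref_pos``, or ``None`` if
        the position lies outside the aligned reference span or inside a
        deletion (gap in the query).
        """
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        q, r = self.query_start, self.ref_start
        for op, ln in self.ops:
            if op == "M":
                if r <= ref_pos < r + ln:
                    return q + (ref_pos - r)
                q += ln
                r += ln
            elif op == "I":
                q += ln
            else:  # D
                if r <= ref_pos < r + ln:
                    return None
                r += ln
        return None


@njit(cache=False)
def _sw_fill(q, r, ma, mi, g):  # pragma: no cover - exercised via wrapper
    nq, nr = q.shape[0], r.shape[0]
    H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    P = np.zeros((nq + 1, nr + 1), dtype=np.uint8)
    OQ = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    OR = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    b_or = 0
    b_oq = 0
    b_len = 0
    for i in range(1, nq + 1):
        qc = q[i - 1]
        for j in range(1, nr + 1):
            s = ma if qc == r[j - 1] else mi
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + g
            left = H[i, j - 1] + g
            # preference: diag > up > left > restart
            v = diag
            p = 1
            if up > v:
                v = up
                p = 2
            if left > v:
                v = left
                p = 3
            if v <= 0:
                H[i, j] = 0
                P[i, j] = 0
                OQ[i, j] = i
                OR[i, j] = j
                continue
            H[i, j] = v
            P[i, j] = p
            if p == 1:
                if H[i - 1, j - 1] == 0:
                    OQ[i, j] = i - 1
                    OR[i, j] = j - 1
                else:
                    OQ[i, j] = OQ[i - 1, j - 1]
                    OR[i, j] = OR[i - 1, j - 1]
            elif p == 2:
                OQ[i, j] = OQ[i - 1, j]
                OR[i, j] = OR[i - 1, j]
            else:
                OQ[i, j] = OQ[i, j - 1]
                OR[i, j] = OR[i, j - 1]
            if v > 0:
                alen = (i - OQ[i, j]) + (j - OR[i, j])
                better = False
                if v > best:
                    better = True
                elif v == best:
                    if OR[i, j] < b_or:
                        better = True
                    elif OR[i, j] == b_or:
                        if OQ[i, j] < b_oq:
                            better = True
                        elif OQ[i, j] == b_oq:
                            if alen < b_len:
                                better = True
                            elif alen == b_len and (i < bi or (i == bi and j < bj)):
                                better = True
                if better:
                    best = v
                    bi = i
                    bj = j
                    b_or = OR[i, j]
                    b_oq = OQ[i, j]
                    b_len = alen
    return H, P, best, bi, bj


@njit(cache=False)
def _sw_traceback(P, bi, bj):  # pragma: no cover - exercised via wrapper
    n = bi + bj
    codes = np.empty(n, dtype=np.uint8)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        codes[k] = p
        k += 1
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return codes[:k][::-1], i, j


@njit(cache=False)
def _sw_score(q, r, ma, mi, g):  # pragma: no cover - exercised via wrapper
    """Score-only Smith-Waterman (no traceback state), for segment screening."""
    nq, nr = q.shape[0], r.shape[0]
    prev = np.zeros(nr + 1, dtype=np.int32)
    cur = np.zeros(nr + 1, dtype=np.int32)
    best = 0
    for i in range(1, nq + 1):
        qc = q[i - 1]
        cur[0] = 0
        for j in range(1, nr + 1):
            s = ma if qc == r[j - 1] else mi
            v = prev[j - 1] + s
            u = prev[j] + g
            if u > v:
                v = u
            l = cur[j - 1] + g
            if l > v:
                v = l
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev, cur = cur, prev
    return best


def sw_score(query: str, ref: str, match: int = 5, mismatch: int = -4, gap: int = -8) -> int:
    """Optimal local-alignment score only (cheaper than a full traceback)."""
    if not query or not ref:
        raise ValueError("empty sequence")
    return int(_sw_score(_encode(query), _encode(ref), match, mismatch, gap))


def smith_waterman(
    query: str,
    ref: str,
    match: int = 5,
    mismatch: int = -4,
    gap: int = -8,
) -> AlignmentResult:
    """Maximal-scoring local alignment of ``query`` against ``ref``.

    Linear gap penalty; deterministic tie-breaking as documented in the
    module docstring. A pair with no positive-scoring cell returns score 0
    and an empty alignment.
    """
    if not query or not ref:
        raise ValueError("empty sequence")
    q = _encode(query)
    r = _encode(ref)
    H, P, best, bi, bj = _sw_fill(q, r, match, mismatch, gap)
    if best <= 0:
        return AlignmentResult(0, 0, 0, 0, 0, ())
    codes, qi, rj = _sw_traceback(P, bi, bj)
    ops: list[tuple[str, int]] = []
    sym = {1: "M", 2: "I", 3: "D"}
    for c in codes:
        ch = sym[int(c)]
        if ops and ops[-1][0] == ch:
            ops[-1] = (ch, ops[-1][1] + 1)
        else:
            ops.append((ch, 1))
    return AlignmentResult(
        score=int(best),
        query_start=int(qi),
        query_end=int(bi),
        ref_start=int(rj),
        ref_end=int(bj),
        ops=tuple(ops),
    )


@njit(cache=False)
def _nw_matches(a, b, ma, mi, g):  # pragma: no cover - exercised via wrapper
    """End-gap-free global alignment; returns matched positions on a best path.

    Among equal-scoring paths the one with the most matches is preferred, so
    the reported count is the maximum achievable at optimal score (and can
    never exceed the shorter sequence length).
    """
    n, m = a.shape[0], b.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        ac = a[i - 1]
        for j in range(1, m + 1):
            ismatch = 1 if ac == b[j - 1] else 0
            s = ma if ismatch == 1 else mi
            bv = S[i - 1, j - 1] + s
            bm = M[i - 1, j - 1] + ismatch
            u = S[i - 1, j] + g
            if u > bv or (u == bv and M[i - 1, j] > bm):
                bv = u
                bm = M[i - 1, j]
            l = S[i, j - 1] + g
            if l > bv or (l == bv and M[i, j - 1] > bm):
                bv = l
                bm = M[i, j - 1]
            S[i, j] = bv
            M[i, j] = bm
    best = S[n, m]
    bm = M[n, m]
    for j in range(m + 1):
        if S[n, j] > best or (S[n, j] == best and M[n, j] > bm):
            best = S[n, j]
            bm = M[n, j]
    for i in range(n + 1):
        if S[i, m] > best or (S[i, m] == best and M[i, m] > bm):
            best = S[i, m]
            bm = M[i, m]
    return bm


def global_matches(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Identical positions in an end-gap-free global alignment of a and b."""
    if not a or not b:
        raise ValueError("empty sequence")
    return int(_nw_matches(_encode(a), _encode(b), match, mismatch, gap))
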