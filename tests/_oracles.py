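"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and pure-Python: direct dynamic
programs, exhaustive scans and exhaustive subset enumeration, sharing no
code with the package implementations they check.
"""

from itertools import combinations
from math import log, exp


def sw_score_bruteforce(query: str, ref: str, match: int, mismatch: int, gap: int) -> int:
    """Plain O(nm) local-alignment DP, score only."""
    nq, nr = len(query), len(ref)
    prev = [0] * (nr + 1)
    best = 0
    for i in range(1, nq + 1):
        cur = [0] * (nr + 1)
        for j in range(1, nr + 1):
            s = match if query[i - 1] == ref[j - 1] else mismatch
            v = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def alignment_score_from_ops(aln, query: str, ref: str,
                             match: int, mismatch: int, gap: int) -> int:
    """Recompute an AlignmentResult's score from its operations."""
    q, r = aln.query_start, aln.ref_start
    score = 0
    for op, ln in aln.ops:
        if op == "M":
            for k in range(ln):
                score += match if query[q + k] == ref[r + k] else mismatch
            q += ln
            r += ln
        elif op == "I":
            score += gap * ln
            q += ln
        else:  # D
            score += gap * ln
            r += ln
    assert q == aln.query_end and r == aln.ref_end
    return score


def enumerate_hill(counts, m: int, q: int) -> float:
    """Exact expectation over all subsets of size m of the n individuals.

    q=0: mean observed richness. q=1: exp of the mean Shannon entropy of
    the subsample (the expected-entropy definition of the interpolated
    exponential Shannon).
    """
    labels = []
    for sp, c in enumerate(counts):
        labels.extend([sp] * c)
    n = len(labels)
    total = 0.0
    nsub = 0
    for subset in combinations(range(n), m):
        tally = {}
        for idx in subset:
            tally[labels[idx]] = tally.get(labels[idx], 0) + 1
        if q == 0:
            total += len(tally)
        elif q == 1:
            total += -sum((k / m) * log(k / m) for k in tally.values())
        else:
            raise ValueError("enumeration oracle supports q in {0, 1}")
        nsub += 1
    mean = total / nsub
    return mean if q == 0 else exp(mean)


IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_window_match(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(window, pattern))


def digest_scan_pattern(seq: str, pattern: str, cut_offset: int):
    """Naive complete digest by window scan; sorted fragment lengths."""
    L, w = len(seq), len(pattern)
    cuts = []
    for i in range(L - w + 1):
        if iupac_window_match(seq[i:i + w], pattern):
            c = i + cut_offset
            if 0 < c < L:
                cuts.append(c)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [L]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _probe_sites(template: str, probe: str, max_mm: int):
    hits = []
    for i in range(len(template) - len(probe) + 1):
        mm = sum(p not in IUPAC_SETS.get(t, "")
                 for t, p in zip(template[i:i + len(probe)], probe))
        if mm <= max_mm:
            hits.append(i)
    return hits


def pcr_scan(template: str, fwd: str, rev: str, max_mm: int = 0,
             max_length: int = 20000):
    """Naive in-silico PCR: all amplicons on both strands, deduplicated,
    forward-primer-first orientation, top strand first in (start, end) order."""
    rev_rc = _revcomp(rev)
    amps = []
    seen = set()
    for strand in (template, _revcomp(template)):
        pairs = []
        for f in _probe_sites(strand, fwd, max_mm):
            for r in _probe_sites(strand, rev_rc, max_mm):
                end = r + len(rev_rc)
                if f <= r and end - f >= len(fwd) + len(rev_rc) and end - f <= max_length:
                    pairs.append((f, end))
        for f, end in sorted(pairs):
            amp = strand[f:end]
            if amp not in seen:
                amps.append(amp)
                seen.add(amp)
    return amps
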