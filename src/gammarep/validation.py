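"""In-silico PCR and restriction digest for locus-structure discrimination.

The duplication question in the chicken TRG locus (a 15 kb block present in
one genome assembly but not in BAC resequencing) was settled at the bench by
PCR across the candidate region followed by a DrdI digest: the two candidate
structures predict different fragment-length multisets. This module is the
computational counterpart — predict amplicons from primer pairs, digest them
with an IUPAC-pattern enzyme, and classify which candidate structure a set
of observed fragment lengths supports.

Enzyme sites are matched exactly per IUPAC code (no mismatches: enzymes do
not cut near-sites); primer sites tolerate a configurable mismatch count.
The packaged DrdI definition is the standard GACNNNN^NNGTC (cut after
position 7); its recognition pattern is reverse-complement symmetric, so the
top strand alone is scanned for cut sites.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .align import revcomp

__all__ = ["EnzymeSpec", "PrimerPair", "DRDI", "in_silico_pcr", "digest", "classify_structure"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class InvalidAlphabetError(ValueError):
    pass


def _check_iupac(seq: str, name: str) -> str:
    s = seq.upper()
    bad = set(s) - set(IUPAC)
    if bad:
        raise InvalidAlphabetError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition pattern and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        _check_iupac(self.recognition, "recognition")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition pattern")

    def _regex(self) -> re.Pattern:
        pat = "".join(f"[{IUPAC[c]}]" for c in self.recognition.upper())
        return re.compile(f"(?={pat})")


DRDI = EnzymeSpec(name="DrdI", recognition="GACNNNNNNGTC", cut_offset=7)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair (each 5'→3' on its own strand)."""

    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self):
        if len(self.forward) < 12 or len(self.reverse) < 12:
            raise ValueError("primers must be >= 12 nt")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def _site_matches(template: str, probe: str, max_mm: int) -> list[int]:
    """Start positions where ``probe`` matches ``template`` with <= max_mm
    mismatches; template IUPAC codes are honoured (probe base must be in the
    code's base set)."""
    hits = []
    lp = len(probe)
    for i in range(len(template) - lp + 1):
        mm = 0
        for a, b in zip(template[i:i + lp], probe):
            if b not in IUPAC.get(a, ""):
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            hits.append(i)
    return hits


def in_silico_pcr(
    template: str,
    primers: PrimerPair,
    max_length: int = 20000,
) -> list[str]:
    """Predict PCR amplicons of ``primers`` on ``template``.

    Every returned amplicon starts with a forward-primer site and ends with
    the reverse complement of the reverse primer (each within
    ``primers.max_mismatches``); all compatible site pairs up to
    ``max_length`` are reported, in deterministic order (by start, then
    end). Both template strands are scanned; amplicons found on the bottom
    strand are reported in forward-primer-first orientation.
    """
    if not template:
        raise ValueError("template is empty")
    template = _check_iupac(template, "template")
    fwd = primers.forward.upper()
    rev_rc = revcomp(primers.reverse.upper())

    def scan(t: str) -> list[tuple[int, int]]:
        f_sites = _site_matches(t, fwd, primers.max_mismatches)
        r_sites = _site_matches(t, rev_rc, primers.max_mismatches)
        pairs = []
        for f in f_sites:
            for r in r_sites:
                end = r + len(rev_rc)
                if end - f >= len(fwd) + len(rev_rc) and f <= r and end - f <= max_length:
                    pairs.append((f, end))
        return sorted(pairs)

    amplicons = [template[f:e] for f, e in scan(template)]
    bottom = revcomp(template)
    seen = set(amplicons)
    for f, e in scan(bottom):
        amp = bottom[f:e]
        if amp not in seen:
            amplicons.append(amp)
            seen.add(amp)
    return amplicons


def digest(amplicon: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths from a complete digest of a linear molecule, sorted.

    Cuts at ``site_start + cut_offset`` for every exact IUPAC match of the
    recognition pattern; fragment lengths always sum to the input length.
    """
    if not amplicon:
        raise ValueError("amplicon is empty")
    amplicon = _check_iupac(amplicon, "amplicon")
    if len(enzyme.recognition) > len(amplicon):
        return [len(amplicon)]
    cuts = sorted(
        m.start() + enzyme.cut_offset
        for m in enzyme._regex().finditer(amplicon)
    )
    cuts = [c for c in cuts if 0 < c < len(amplicon)]
    bounds = [0] + cuts + [len(amplicon)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def classify_structure(
    observed: list[int],
    candidates: dict[str, list[int]],
    tolerance: int = 0,
) -> str:
    """Pick the unique candidate structure whose expected fragment multiset
    matches ``observed`` within ``tolerance`` nt per fragment; ``"ambiguous"``
    if none or several match."""
    if not observed:
        raise ValueError("observed fragment list is empty")
    if len(candidates) < 2:
        raise ValueError("need at least two candidate structures")

    def matches(exp: list[int]) -> bool:
        if len(exp) != len(observed):
            return False
        remaining = Counter(sorted(exp))
        for o in sorted(observed):
            hit = None
            for e in remaining:
                if remaining[e] and abs(e - o) <= tolerance:
                    hit = e
                    break
            if hit is None:
                return False
            remaining[hit] -= 1
        return True

    winners = [label for label in sorted(candidates) if matches(candidates[label])]
    return winners[0] if len(winners) == 1 else "ambiguous"
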