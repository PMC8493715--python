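"""Recombination-signal-sequence scoring and the usage regression.

V(D)J recombination is directed by the recombination signal sequence (RSS):
a conserved heptamer, a 12 or 23 nt spacer, and a conserved nonamer flanking
each V and J segment. RSS quality partly predicts how often a V gene is
rearranged. The scorer here is a position-weight-matrix log-odds model
trained on a set of RSS sequences: per heptamer/nonamer position,
log(base frequency with pseudocount / background). Scores are on an
arbitrary log-odds scale — higher is better, the training consensus attains
the model maximum — and are *not* comparable to RIC scores from trained
Bayesian models (whose published chicken values lie between -70 and -40 on
a -1000..0 scale); externally computed RIC scores can be supplied as a TSV
to rerun the regression on that scale.

The regression is an ordinary least squares of per-V thymic usage
proportion on RSS score, reporting slope, intercept, R-squared and the
two-sided p-value for the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["RSSModel", "train_rss_model", "score_rss", "usage_regression"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
SCORE_FLOOR = -20.0  # floor for bases unseen in training


@dataclass(frozen=True)
class RSSModel:
    """Log-odds matrices (4 x length) for heptamer and nonamer; the spacer is
    length-checked but not scored."""

    heptamer: np.ndarray
    nonamer: np.ndarray
    spacer_length: int
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.heptamer.shape != (4, 7) or self.nonamer.shape != (4, 9):
            raise ValueError("heptamer must be 4x7 and nonamer 4x9")
        if self.spacer_length not in (12, 23):
            raise ValueError("spacer_length must be 12 or 23")
        if not (np.isfinite(self.heptamer).all() and np.isfinite(self.nonamer).all()):
            raise ValueError("log-odds matrices must be finite")

    @property
    def rss_length(self) -> int:
        return 7 + self.spacer_length + 9

    def max_score(self) -> float:
        return float(self.heptamer.max(axis=0).sum() + self.nonamer.max(axis=0).sum())

    def consensus(self) -> str:
        bases = "ACGT"
        hep = "".join(bases[i] for i in self.heptamer.argmax(axis=0))
        non = "".join(bases[i] for i in self.nonamer.argmax(axis=0))
        return hep + "N" * self.spacer_length + non


def _pwm(seqs: list[str], length: int, background, pseudocount: float) -> np.ndarray:
    counts = np.full((4, length), pseudocount)
    for s in seqs:
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    lod = np.log(freqs / np.asarray(background)[:, None])
    return np.maximum(lod, SCORE_FLOOR)


def train_rss_model(
    training_seqs: list[str],
    spacer_length: int = 23,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.5,
) -> RSSModel:
    """Fit the PWM log-odds model from full-length RSS training sequences."""
    want = 7 + spacer_length + 9
    if not training_seqs:
        raise ValueError("no training sequences")
    for s in training_seqs:
        if len(s) != want:
            raise ValueError(f"training RSS length {len(s)} != {want}")
    heps = [s[:7].upper() for s in training_seqs]
    nons = [s[-9:].upper() for s in training_seqs]
    return RSSModel(
        heptamer=_pwm(heps, 7, background, pseudocount),
        nonamer=_pwm(nons, 9, background, pseudocount),
        spacer_length=spacer_length,
        background=background,
    )


def score_rss(model: RSSModel, rss: str) -> float:
    """Sum of per-position log-odds over heptamer and nonamer.

    The spacer is ignored; a base unseen in training contributes the
    floored log-odds rather than -inf.
    """
    rss = rss.upper()
    if len(rss) != model.rss_length:
        raise ValueError(f"RSS length {len(rss)} != expected {model.rss_length}")
    score = 0.0
    for j, b in enumerate(rss[:7]):
        if b not in _BASE_INDEX:
            raise ValueError(f"non-ACGT base {b!r} in heptamer")
        score += model.heptamer[_BASE_INDEX[b], j]
    for j, b in enumerate(rss[-9:]):
        if b not in _BASE_INDEX:
            raise ValueError(f"non-ACGT base {b!r} in nonamer")
        score += model.nonamer[_BASE_INDEX[b], j]
    return float(score)


def usage_regression(
    scores: dict[str, float],
    usage: dict[str, float],
) -> dict[str, float]:
    """OLS of thymic usage proportion on RSS score over the shared V genes.

    Returns slope, intercept, r_squared and the two-sided p-value for the
    slope. Requires >= 3 paired points and non-constant scores.
    """
    common = sorted(set(scores) & set(usage))
    if len(common) < 3:
        raise ValueError("need at least 3 paired (score, usage) points")
    x = np.array([scores[v] for v in common], dtype=float)
    y = np.array([usage[v] for v in common], dtype=float)
    if (y < 0).any() or (y > 1).any():
        raise ValueError("usage proportions must lie in [0, 1]")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in scores: slope undefined")
    fit = linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "p_value": float(fit.pvalue),
        "n": len(common),
    }
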