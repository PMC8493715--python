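"""Clonotype tables and TRGV usage profiles with bootstrap intervals.

A clonotype is a (V group, junction nucleotide sequence) pair within one
bird and tissue. Usage proportions are computed per bird x tissue and
summarised across birds with an unweighted mean (each bird counts equally,
matching the bird-as-random-effect logic of a mixed model); 95% intervals
come from a hierarchical bootstrap that resamples birds with replacement
and averages on the logit scale, back-transforming the percentile bounds.
Between-group contrasts use the bootstrap distribution of the difference of
logit means; these are bootstrap p-values, not mixed-model Satterthwaite
p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "build_clonotype_table",
    "usage_proportions",
    "bootstrap_ci",
    "bootstrap_contrast",
]

CLONOTYPE_COLUMNS = ["line", "bird_id", "tissue", "v_group", "junction_nt", "read_count"]


def build_clonotype_table(
    rearrangements: pd.DataFrame,
    filter: str = "in_frame",
) -> pd.DataFrame:
    """Aggregate annotated rearrangements into clonotype counts.

    Keeps reads passing ``filter`` (``"in_frame"`` — the study's criterion —
    or ``"productive"``, which additionally drops junctions with stop
    codons) whose V call was retained (unique call or a retained ambiguous
    group). Rows with missing bird/tissue metadata are reported and
    skipped. Counts aggregate identical (v_group, junction) within bird x
    tissue.
    """
    if filter not in ("in_frame", "productive"):
        raise ValueError("filter must be 'in_frame' or 'productive'")
    df = rearrangements
    keep = (df["junction"] != "") & (df["v_call"] != "")
    keep &= ~df["flags"].str.contains("ambiguous_v_excluded", na=False)
    keep &= df["vj_in_frame"] if filter == "in_frame" else df["productive"]
    df = df[keep]
    missing = (df["bird_id"] == "") | (df["tissue"] == "")
    if missing.any():
        warnings.warn(f"{int(missing.sum())} rows lack bird/tissue metadata; skipped")
        df = df[~missing]
    out = (df.groupby(["line", "bird_id", "tissue", "v_call", "junction"], sort=True)
           .size().reset_index(name="read_count")
           .rename(columns={"v_call": "v_group", "junction": "junction_nt"}))
    return out[CLONOTYPE_COLUMNS]


def clonotype_table_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """The simulator truth margins in clonotype-table form (oracle input)."""
    out = (truth.groupby(["line", "bird_id", "tissue", "v_group", "junction_nt"])
           ["read_count"].sum().reset_index())
    return out[CLONOTYPE_COLUMNS]


def _per_bird_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Long frame of per bird x tissue V-group proportions (sum to 1)."""
    counts = (table.groupby(["line", "bird_id", "tissue", "v_group"])["read_count"]
              .sum().reset_index())
    totals = counts.groupby(["line", "bird_id", "tissue"])["read_count"].transform("sum")
    counts["proportion"] = counts["read_count"] / totals
    counts["sample_total"] = totals
    return counts


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1 / (1 + np.exp(-x))


def _adjust(p: np.ndarray, totals: np.ndarray | None) -> np.ndarray:
    """Haldane–Anscombe-style continuity adjustment for 0/1 proportions:
    add 0.5 reads to the numerator and 1 to the denominator."""
    p = np.asarray(p, dtype=float)
    if totals is None:
        totals = np.full(p.shape, 1000.0)
    totals = np.asarray(totals, dtype=float)
    out = p.copy()
    edge = (p <= 0) | (p >= 1)
    out[edge] = (p[edge] * totals[edge] + 0.5) / (totals[edge] + 1.0)
    return out


def bootstrap_ci(
    proportions: np.ndarray,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
    totals: np.ndarray | None = None,
) -> tuple[float, float]:
    """95% CI for the mean of per-bird proportions, logit-scale bird bootstrap.

    Birds are resampled with replacement; each replicate's statistic is the
    mean of logit-transformed proportions; the 2.5/97.5 percentiles are
    back-transformed to the original scale. ``totals`` (per-bird read
    totals) feed the continuity adjustment applied to proportions of
    exactly 0 or 1. A single bird yields a degenerate CI with a warning.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("no proportions given")
    if p.size == 1:
        warnings.warn("single bird: degenerate confidence interval")
        return float(p[0]), float(p[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = _logit(_adjust(p, totals))
    idx = rng.integers(0, z.size, size=(replicates, z.size))
    means = z[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(_expit(lo)), float(_expit(hi))


def bootstrap_contrast(
    proportions_a: np.ndarray,
    proportions_b: np.ndarray,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided bootstrap p-value for a difference in logit-mean proportions.

    Resamples birds within each group independently and asks how often the
    bootstrap difference distribution crosses zero (labelled a bootstrap
    p-value: it is not a mixed-model test).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    za = _logit(_adjust(np.asarray(proportions_a, float), None))
    zb = _logit(_adjust(np.asarray(proportions_b, float), None))
    da = za[rng.integers(0, za.size, size=(replicates, za.size))].mean(axis=1)
    db = zb[rng.integers(0, zb.size, size=(replicates, zb.size))].mean(axis=1)
    diff = da - db
    frac = min((diff > 0).mean(), (diff < 0).mean())
    return float(min(1.0, 2 * frac + 1 / replicates))


def usage_proportions(
    table: pd.DataFrame,
    replicates: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per tissue x V group usage: unweighted bird mean with bootstrap CI.

    Per bird and tissue the V-group proportion is reads in the group over
    total reads; the tissue summary is the unweighted mean over birds.
    Tissues with zero reads are omitted with a warning. Returns a tidy
    frame: line, tissue, v_group, mean_proportion, ci_lower, ci_upper,
    n_birds.
    """
    per_bird = _per_bird_proportions(table)
    if per_bird.empty:
        warnings.warn("empty clonotype table")
        return pd.DataFrame(columns=["line", "tissue", "v_group", "mean_proportion",
                                     "ci_lower", "ci_upper", "n_birds"])
    rng = np.random.default_rng(seed)
    rows = []
    for (line, tissue), sub in per_bird.groupby(["line", "tissue"], sort=True):
        birds = sorted(sub["bird_id"].unique())
        totals = sub.groupby("bird_id")["sample_total"].first()
        for v_group, vsub in sub.groupby("v_group", sort=True):
            # birds without this V group contribute proportion 0
            p = vsub.set_index("bird_id")["proportion"].reindex(birds).fillna(0.0)
            t = totals.reindex(birds).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lo, hi = bootstrap_ci(p.to_numpy(), replicates, rng, totals=t)
            rows.append({
                "line": line, "tissue": tissue, "v_group": v_group,
                "mean_proportion": float(p.mean()),
                "ci_lower": lo, "ci_upper": hi, "n_birds": len(birds),
            })
    return pd.DataFrame(rows)
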