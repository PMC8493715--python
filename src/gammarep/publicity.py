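"""Public/private clonotype analysis.

A clonotype — by default the pair (V group, junction nucleotide sequence) —
is *public* when it appears in a defined fraction of the birds of a line,
pooling presence over all tissues at any read frequency. Penetrance bins
are mutually exclusive for stacked displays (p100 means all birds; p80
means [0.8, 1.0); p60 means [0.6, 0.8); otherwise private) and cumulative
for between-line sharing: a clone public at some level in line A counts as
shared when it reaches the *same level or higher* in line B. Sharing is
reported either read-weighted (each clone weighted by its share of the
line's public repertoire at that level) or unweighted (clones counted
equally). For between-line comparisons the larger line is down-sampled to
the smaller line's bird count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "PublicityRecord",
    "compute_publicity",
    "public_fraction_by_v",
    "cross_line_sharing",
    "downsample_birds",
    "compare_publicity_between_lines",
]

BINS = ("private", "p60", "p80", "p100")
_LEVEL_RANK = {"p60": 1, "p80": 2, "p100": 3}


@dataclass(frozen=True)
class PublicityRecord:
    key: tuple  # (v_group, junction_nt) by default
    birds_present: frozenset
    penetrance: float
    bin: str
    read_share_per_bird: tuple  # ((bird_id, share), ...)


def _bin_for(penetrance: float, thresholds=(0.6, 0.8, 1.0)) -> str:
    t60, t80, t100 = thresholds
    if penetrance >= t100:
        return "p100"
    if penetrance >= t80:
        return "p80"
    if penetrance >= t60:
        return "p60"
    return "private"


def compute_publicity(
    table: pd.DataFrame,
    line: str,
    thresholds: tuple[float, float, float] = (0.6, 0.8, 1.0),
    key_cols: tuple[str, ...] = ("v_group", "junction_nt"),
) -> list[PublicityRecord]:
    """Penetrance and publicity bin for every clonotype of a line.

    Presence is pooled over all tissues of a bird at any frequency; the
    penetrance denominator is all birds of the line. The clonotype key
    includes the V group by default, so identical junctions on different V
    genes are distinct clones (pass ``key_cols=("junction_nt",)`` for
    global-junction publicity).
    """
    sub = table[table["line"] == line]
    birds = sorted(sub["bird_id"].unique())
    if len(birds) < 2:
        raise ValueError(f"publicity undefined for line {line!r}: needs >= 2 birds")
    n_birds = len(birds)
    per_bird = (sub.groupby(list(key_cols) + ["bird_id"])["read_count"]
                .sum().reset_index())
    bird_totals = per_bird.groupby("bird_id")["read_count"].sum()
    records = []
    for key, kgrp in per_bird.groupby(list(key_cols), sort=True):
        present = frozenset(kgrp["bird_id"])
        pen = len(present) / n_birds
        shares = tuple(
            (b, float(c / bird_totals[b]))
            for b, c in zip(kgrp["bird_id"], kgrp["read_count"])
        )
        records.append(PublicityRecord(
            key=key if isinstance(key, tuple) else (key,),
            birds_present=present,
            penetrance=pen,
            bin=_bin_for(pen, thresholds),
            read_share_per_bird=shares,
        ))
    return records


def public_fraction_by_v(
    records: list[PublicityRecord],
    table: pd.DataFrame,
    line: str,
) -> pd.DataFrame:
    """Read-weighted share of each publicity bin within each V group.

    Shares sum to 1 over {private, p60, p80, p100} per V group (the stacked
    display of the repertoire's public composition).
    """
    bin_of = {r.key: r.bin for r in records}
    sub = table[table["line"] == line].copy()
    sub["bin"] = [bin_of[(v, j)] for v, j in zip(sub["v_group"], sub["junction_nt"])]
    counts = sub.groupby(["v_group", "bin"])["read_count"].sum().unstack(fill_value=0)
    for b in BINS:
        if b not in counts.columns:
            counts[b] = 0
    shares = counts[list(BINS)].div(counts[list(BINS)].sum(axis=1), axis=0)
    shares.columns.name = None
    return shares.reset_index()


def _public_read_weight(records, table, line) -> pd.DataFrame:
    sub = table[table["line"] == line]
    tot = (sub.groupby(["v_group", "junction_nt"])["read_count"].sum())
    return tot


def cross_line_sharing(
    records_a: list[PublicityRecord],
    records_b: list[PublicityRecord],
    mode: str = "weighted",
    table_a: pd.DataFrame | None = None,
    line_a: str | None = None,
) -> dict[str, float | None]:
    """Per publicity level, the proportion of line A's public repertoire
    shared with line B.

    A clone public at level L in A is shared when it attains level >= L in
    B (cumulative ordering p100 > p80 > p60). ``weighted`` mode weights
    each clone by its read share of A's public repertoire at that level
    (requires ``table_a``/``line_a``); ``unweighted`` counts clones
    equally. Levels with no public clones in A report ``None``.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    rank_b = {r.key: _LEVEL_RANK.get(r.bin, 0) for r in records_b}
    weights = None
    if mode == "weighted":
        if table_a is None or line_a is None:
            raise ValueError("weighted mode needs table_a and line_a")
        weights = _public_read_weight(records_a, table_a, line_a)
    out: dict[str, float | None] = {}
    for level, lrank in _LEVEL_RANK.items():
        # cumulative: clones public at >= this level in A
        clones = [r for r in records_a if _LEVEL_RANK.get(r.bin, 0) >= lrank]
        if not clones:
            out[level] = None
            continue
        if mode == "unweighted":
            shared = sum(rank_b.get(r.key, 0) >= lrank for r in clones)
            out[level] = shared / len(clones)
        else:
            w = np.array([weights.get(r.key, 0) for r in clones], dtype=float)
            total = w.sum()
            shared = sum(wi for r, wi in zip(clones, w)
                         if rank_b.get(r.key, 0) >= lrank)
            out[level] = float(shared / total) if total > 0 else None
    return out


def downsample_birds(
    table: pd.DataFrame,
    line: str,
    n_target: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Keep a uniform random subset of ``n_target`` birds of ``line`` (all
    their reads retained); other lines pass through unchanged."""
    birds = sorted(table.loc[table["line"] == line, "bird_id"].unique())
    if n_target > len(birds):
        raise ValueError(f"line {line!r} has only {len(birds)} birds")
    if n_target == len(birds):
        return table.copy()
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(birds, size=n_target, replace=False))
    mask = (table["line"] != line) | table["bird_id"].isin(keep)
    return table[mask].reset_index(drop=True)


def compare_publicity_between_lines(
    table: pd.DataFrame,
    line_a: str,
    line_b: str,
    bin: str = "p100",
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-test comparison of per-V public read shares between two lines.

    The larger line is first down-sampled to the smaller line's bird count;
    publicity is then recomputed per line and the distributions of per-V
    ``bin`` read shares are contrasted with a Wilcoxon rank-sum
    (Mann–Whitney) test. Returns a tidy frame of per-V shares for both
    lines with the test result in ``attrs["pvalue"]``; when several bins
    are tested, collect the p-values and apply Benjamini–Hochberg via
    :func:`statsmodels.stats.multitest.multipletests`.
    """
    n_a = table.loc[table["line"] == line_a, "bird_id"].nunique()
    n_b = table.loc[table["line"] == line_b, "bird_id"].nunique()
    n = min(n_a, n_b)
    t = downsample_birds(table, line_a if n_a > n else line_b, n, seed=seed)
    rec_a = compute_publicity(t, line_a)
    rec_b = compute_publicity(t, line_b)
    fa = public_fraction_by_v(rec_a, t, line_a).set_index("v_group")[bin]
    fb = public_fraction_by_v(rec_b, t, line_b).set_index("v_group")[bin]
    common = sorted(set(fa.index) & set(fb.index))
    out = pd.DataFrame({"v_group": common,
                        f"{line_a}_{bin}_share": fa.reindex(common).to_numpy(),
                        f"{line_b}_{bin}_share": fb.reindex(common).to_numpy()})
    if len(common) >= 2:
        stat, p = mannwhitneyu(out.iloc[:, 1], out.iloc[:, 2], alternative="two-sided")
        out.attrs["pvalue"] = float(p)
        out.attrs["statistic"] = float(stat)
    return out
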