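import numpy as np
import pandas as pd
import pytest

from gammarep.diversity import (
    AbundanceVector,
    abundances_from_table,
    coverage_estimate,
    diversity_bootstrap_ci,
    hill_at_coverage,
    hill_at_size,
    hill_observed,
)
from gammarep.diversity import _hill_interpolated  # continuity check at m = n

from _oracles import enumerate_hill

VECTORS = [[1, 1, 2], [3, 2, 1, 1], [2, 2], [5, 1], [2, 2, 2, 1]]


def test_abundance_vector_validation():
    with pytest.raises(ValueError):
        AbundanceVector([])
    with pytest.raises(ValueError):
        AbundanceVector([2, 0, 1])
    x = AbundanceVector([1, 3, 2, 1])
    assert (x.n, x.s_obs) == (7, 4)
    assert (x.f(1), x.f(2), x.f(3), x.f(4)) == (2, 1, 1, 0)


def test_coverage_hand_values():
    # Good-Turing full-sample coverage of [1,1,2]:
    # 1 - (f1/n) * ((n-1) f1 / ((n-1) f1 + 2 f2)) = 1 - (2/4)*(6/8) = 0.625
    assert coverage_estimate(AbundanceVector([1, 1, 2])) == pytest.approx(0.625)
    # interpolated coverage of [2,2] at m=2:
    # 1 - sum (Xi/n) C(n-Xi,2)/C(n-1,2) = 1 - 2*(2/4)*(1/3) = 2/3
    assert coverage_estimate(AbundanceVector([2, 2]), 2) == pytest.approx(2 / 3)


def test_coverage_monotone_in_m():
    for counts in VECTORS:
        x = AbundanceVector(counts)
        cs = [coverage_estimate(x, m) for m in range(1, x.n + 4)]
        assert all(b >= a - 1e-12 for a, b in zip(cs, cs[1:]))
        assert all(0 <= c <= 1 for c in cs)
    with pytest.raises(ValueError):
        coverage_estimate(AbundanceVector([1, 2]), 0)


def test_coverage_complete_sample():
    x = AbundanceVector([3, 4])  # f1 = 0: no unseen mass
    assert coverage_estimate(x) == 1.0
    assert coverage_estimate(x, x.n + 5) == 1.0


def test_hill_observed():
    x = AbundanceVector([1, 1, 1])
    for q in (0, 0.5, 1, 2, 3):
        assert hill_observed(x, q) == pytest.approx(3.0)
    y = AbundanceVector([1, 1, 2])
    assert hill_observed(y, 0) == 3
    assert hill_observed(y, 2) == pytest.approx(1 / (0.25 ** 2 + 0.25 ** 2 + 0.5 ** 2))
    with pytest.raises(ValueError):
        hill_observed(y, -1)


def test_interpolation_matches_exhaustive_enumeration():
    """q=0 interpolation equals the exact mean subset richness; q=1 equals the
    exponential of the exact mean subset entropy (n <= 8, all subset sizes)."""
    for counts in VECTORS:
        x = AbundanceVector(counts)
        for m in range(1, x.n):
            est0 = hill_at_size(x, m, 0)
            assert est0.value == pytest.approx(enumerate_hill(counts, m, 0), abs=1e-10)
            assert est0.method == "interpolated"
            est1 = hill_at_size(x, m, 1)
            assert est1.value == pytest.approx(enumerate_hill(counts, m, 1), abs=1e-10)


def test_interpolation_continuous_at_full_size():
    for counts in VECTORS:
        x = AbundanceVector(counts)
        for q in (0, 1, 2):
            assert _hill_interpolated(x, x.n, q) == pytest.approx(
                hill_observed(x, q), abs=1e-10)
            assert hill_at_size(x, x.n, q).method == "observed"


def test_extrapolation_behaviour():
    x = AbundanceVector([1, 1, 2, 2, 3])  # f1 = 2, f2 = 2
    for q in (0, 1, 2):
        vals = [hill_at_size(x, m, q).value for m in range(x.n, x.n + 30)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        assert hill_at_size(x, x.n + 5, q).method == "extrapolated"
    # q=0 extrapolation is bounded by the Chao1 asymptote S_obs + f1^2/(2 f2)
    asy = x.s_obs + 2 ** 2 / (2 * 2)
    assert hill_at_size(x, 10 ** 6, 0).value <= asy + 1e-9


def test_extrapolation_complete_sample_flagged():
    x = AbundanceVector([2, 2])  # f1 = 0
    est = hill_at_size(x, 10, 0)
    assert est.value == 2.0
    assert "complete sample" in est.method


def test_hill_monotone_in_q():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = rng.integers(1, 10, size=rng.integers(2, 15))
        x = AbundanceVector(counts)
        qs = [0, 0.5, 1, 1.5, 2, 3]
        obs = [hill_observed(x, q) for q in qs]
        assert all(b <= a + 1e-9 for a, b in zip(obs, obs[1:]))
        m = max(2, x.n // 2)
        std = [hill_at_size(x, m, q).value for q in (0, 1, 2)]
        assert std[0] + 1e-9 >= std[1] >= std[2] - 1e-9


def test_hill_at_coverage_picks_smallest_m():
    x = AbundanceVector([8, 4, 2, 1, 1, 1, 1])
    target = 0.5
    est = hill_at_coverage(x, target, 0)
    assert est.coverage >= target
    if est.m > 1:
        assert coverage_estimate(x, est.m - 1) < target


def test_hill_at_coverage_extrapolates_when_needed():
    x = AbundanceVector([1, 1, 2, 2])
    target = 0.95  # full-sample coverage is below this
    assert coverage_estimate(x) < target
    est = hill_at_coverage(x, target, 0)
    assert est.m > x.n
    assert est.method == "extrapolated"


def test_hill_at_coverage_unreachable_target_flagged():
    x = AbundanceVector([1, 5])  # f1 = 1, f2 = 0: coverage cannot be extrapolated up
    est = hill_at_coverage(x, 0.95, 0)
    assert "unreachable" in est.method
    assert est.value == 2.0
    with pytest.raises(ValueError):
        hill_at_coverage(x, 1.5, 0)


def test_diversity_bootstrap_ci():
    x = AbundanceVector([10, 8, 5, 3, 2, 1, 1, 1])
    lo, hi = diversity_bootstrap_ci(x, target_coverage=0.5, q=1,
                                    replicates=100, seed=0)
    assert lo <= hi


def test_abundances_from_table():
    table = pd.DataFrame({
        "line": ["L"] * 5,
        "bird_id": ["b1", "b1", "b1", "b2", "b2"],
        "tissue": ["thymus"] * 5,
        "v_group": ["V1", "V1", "V2", "V1", "V1"],
        "junction_nt": ["AAA", "AAA", "CCC", "AAA", "GGG"],
        "read_count": [3, 2, 4, 1, 2],
    })
    per_bird = abundances_from_table(table)
    # bird b1: clones (V1,AAA)=5 and (V2,CCC)=4; bird b2: (V1,AAA)=1, (V1,GGG)=2
    assert sorted(per_bird[("L", "thymus", "b1")].x.tolist()) == [4, 5]
    assert sorted(per_bird[("L", "thymus", "b2")].x.tolist()) == [1, 2]
    pooled = abundances_from_table(table, within_bird=False)
    assert sorted(pooled[("L", "thymus")].x.tolist()) == [2, 4, 6]
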