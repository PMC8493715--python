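import math

import numpy as np
import pandas as pd
import pytest

from gammarep.annotate import annotate
from gammarep.demux import demultiplex
from gammarep.simulate import (
    PublicCloneSpec,
    SimulationConfig,
    default_v_usage,
    expected_groups,
    make_junction,
    simulate_reads,
    simulate_repertoire,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(error_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(insert_base_probs=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(v_usage={"TRGV3.3": 0.5})
    with pytest.raises(ValueError):
        PublicCloneSpec("TRGV3.3", penetrance=0.0)
    with pytest.raises(ValueError):
        PublicCloneSpec("TRGV3.3", penetrance=0.5, expansion_factor=0.5)


def test_default_v_usage_sums_to_one(reference):
    usage = default_v_usage(reference)
    assert abs(sum(usage.values()) - 1) < 1e-12
    assert usage["TRGV3.3"] == 0.35
    # only expressed (functional) genes receive mass
    for vid in usage:
        assert reference[vid].functional_status == "functional"


def test_expected_groups_contains_retained_groups(reference):
    groups = expected_groups(reference)
    assert groups["TRGV2.7"] == "TRGV2.7/2.18"
    assert groups["TRGV2.18"] == "TRGV2.7/2.18"
    assert groups["TRGV2.4"] == "TRGV2.4/2.8/2.14/2.19"
    assert groups["TRGV3.3"] == "TRGV3.3"


def _small_cfg(**kw):
    base = dict(seed=5, birds_per_line=2, tissues=("thymus",),
                reads_per_sample=200, clones_per_bird=15)
    base.update(kw)
    return SimulationConfig(**base)


def test_repertoire_read_counts_sum_per_sample(reference):
    cfg = _small_cfg()
    truth, clones = simulate_repertoire(cfg, reference)
    sums = truth.groupby("sample_id")["read_count"].sum()
    assert (sums == cfg.reads_per_sample).all()
    assert set(truth["tissue"]) == {"thymus"}
    assert truth["bird_id"].nunique() == 2


def test_junctions_preserve_anchors(reference):
    truth, _ = simulate_repertoire(_small_cfg(), reference)
    for row in truth.itertuples(index=False):
        j = reference[row.j_id]
        anchor = j.sequence[j.junction_anchor_offset:j.junction_anchor_offset + 3]
        assert row.junction_nt.startswith("TGT")
        assert row.junction_nt.endswith(anchor)


def test_make_junction(reference):
    v, j = "TRGV3.1", "TRGJ1"
    junction = make_junction(reference, v, j, insert="GGGACC", trim_v=2, trim_j=1)
    vs, js = reference[v], reference[j]
    assert junction == (vs.sequence[vs.junction_anchor_offset:-2] + "GGGACC"
                        + js.sequence[1:js.junction_anchor_offset + 3])


def test_public_clone_planting(reference):
    specs = (PublicCloneSpec("TRGV3.1", penetrance=1.0, j_id="TRGJ1",
                             junction_nt=make_junction(reference, "TRGV3.1", "TRGJ1",
                                                       insert="GGGACCTTT")),
             PublicCloneSpec("TRGV1.3", penetrance=0.5))
    cfg = _small_cfg(birds_per_line=4, public_pool=specs, reads_per_sample=2000)
    truth, clones = simulate_repertoire(cfg, reference)
    pub = truth[truth["is_public"]]
    by_clone = pub.groupby("clone_id")["bird_id"].nunique()
    assert by_clone["pub0"] == 4                      # all birds
    assert by_clone["pub1"] == math.ceil(0.5 * 4)     # ceil(penetrance * n)
    # planted junction is nucleotide-identical across birds
    assert pub[pub["clone_id"] == "pub0"]["junction_nt"].nunique() == 1
    assert (pub[pub["clone_id"] == "pub0"]["v_id"] == "TRGV3.1").all()


def test_simulation_is_deterministic(reference):
    cfg = _small_cfg()
    t1, c1 = simulate_repertoire(cfg, reference)
    t2, c2 = simulate_repertoire(cfg, reference)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(c1, c2)
    r1, s1, tr1 = simulate_reads(t1, reference, cfg)
    r2, s2, tr2 = simulate_reads(t2, reference, cfg)
    assert [(a.read_id, a.sequence) for a in r1] == \
        [(b.read_id, b.sequence) for b in r2]
    pd.testing.assert_frame_equal(s1.rows, s2.rows)
    pd.testing.assert_frame_equal(tr1, tr2)


def test_different_seed_changes_output(reference):
    t1, _ = simulate_repertoire(_small_cfg(seed=5), reference)
    t2, _ = simulate_repertoire(_small_cfg(seed=6), reference)
    assert not t1.equals(t2)


def test_reads_structure(reference):
    cfg = _small_cfg()
    truth, _ = simulate_repertoire(cfg, reference)
    reads, sheet, truth_reads = simulate_reads(truth, reference, cfg)
    assert len(reads) == 2 * cfg.reads_per_sample
    assert len(truth_reads) == len(reads)
    # adapter + barcode layout
    bc_of = sheet.barcode_to_sample
    for r in reads[:50]:
        assert r.sequence.startswith("AAGCAGTGGTATCAACGCAGAG")
        bc = r.sequence[22:30]
        assert bc in bc_of
    # barcodes pairwise Hamming distance >= 3
    bcs = list(bc_of)
    for i, a in enumerate(bcs):
        for b in bcs[i + 1:]:
            assert sum(x != y for x, y in zip(a, b)) >= 3


def test_error_rate_perturbs_reads(reference):
    cfg0 = _small_cfg()
    truth, _ = simulate_repertoire(cfg0, reference)
    clean, _, _ = simulate_reads(truth, reference, cfg0)
    noisy, _, _ = simulate_reads(truth, reference, _small_cfg(error_rate=0.05))
    diffs = sum(a.sequence != b.sequence for a, b in zip(clean, noisy))
    assert diffs > len(clean) * 0.9


def test_reverse_fraction(reference):
    cfg = _small_cfg(reverse_fraction=0.5)
    truth, _ = simulate_repertoire(cfg, reference)
    reads, _, _ = simulate_reads(truth, reference, cfg)
    n_rev = sum(not r.sequence.startswith("AAGCAGTGG") for r in reads)
    assert 0.3 < n_rev / len(reads) < 0.7


def test_recovery_with_sequencing_error(reference):
    """With 1% per-base error, V and J calls should still be nearly always
    correct (junction *sequences* may carry the errors)."""
    hits = 0
    total = 0
    for seed in (11, 12, 13):
        cfg = SimulationConfig(seed=seed, birds_per_line=1, tissues=("thymus",),
                               reads_per_sample=120, clones_per_bird=12,
                               error_rate=0.01)
        truth, _ = simulate_repertoire(cfg, reference)
        reads, sheet, truth_reads = simulate_reads(truth, reference, cfg)
        streams, _ = demultiplex(reads, sheet, max_mismatches=1)
        airr, _ = annotate(streams, reference)
        merged = airr.set_index("sequence_id").join(
            truth_reads.set_index("read_id"), rsuffix="_t")
        ok = (merged["v_call"] == merged["v_group"]) & \
             (merged["j_call"] == merged["j_id"])
        hits += int(ok.sum())
        total += len(truth_reads)
    assert hits / total >= 0.95
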