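import pandas as pd
import pytest

from gammarep.align import revcomp
from gammarep.annotate import (
    AnnotateConfig,
    annotate,
    assign_segment,
    classify_productive,
    extract_junction,
    format_group,
    smith_waterman,
)
from gammarep.demux import ReadRecord
from gammarep.reference import GeneSegment, LocusAnnotation

V1_SEQ = "ACGGATTCAGGCTTACAGGCTAACGGTCAT" + "TGT" + "ACCGGTA"
V2_SEQ = "TTGACCAGTCAACGGATGCCATTGCAGGCA" + "TGT" + "GACCTTA"
J1_SEQ = "GGATCCTTAAGG" + "TTT" + "CAGGTTCAAGGCACC"
C_SEQ = "CATCGGACTTGACCATTGCAGACCTTGAGG"


@pytest.fixture(scope="module")
def mini_ref():
    segs = [
        GeneSegment(id="TRGV1.1", segment_type="V", sequence=V1_SEQ,
                    family="TRGV1", junction_anchor_offset=30,
                    locus_start=0, locus_end=40),
        GeneSegment(id="TRGV2.1", segment_type="V", sequence=V2_SEQ,
                    family="TRGV2", junction_anchor_offset=30,
                    locus_start=100, locus_end=140),
        GeneSegment(id="TRGV2.2", segment_type="V", sequence=V2_SEQ,
                    family="TRGV2", family_index=2, junction_anchor_offset=30,
                    locus_start=200, locus_end=240),
        GeneSegment(id="TRGJ1", segment_type="J", sequence=J1_SEQ,
                    junction_anchor_offset=12, locus_start=300, locus_end=330),
        GeneSegment(id="TRGC", segment_type="C", sequence=C_SEQ,
                    locus_start=400, locus_end=430),
    ]
    return LocusAnnotation(segments=segs)


def _read_seq(v_seq, insert, j_seq=J1_SEQ):
    return v_seq + insert + j_seq + C_SEQ


def test_format_group():
    assert format_group(["TRGV2.7", "TRGV2.18"]) == "TRGV2.7/2.18"
    assert format_group(["TRGV2.4", "TRGV2.8", "TRGV2.14", "TRGV2.19"]) == \
        "TRGV2.4/2.8/2.14/2.19"
    assert format_group(["TRGJ1"]) == "TRGJ1"


def test_classify_productive():
    assert classify_productive("TGTGCAGGGTTT") == (True, False, True)
    assert classify_productive("TGTTAAGGGTTT") == (True, True, False)   # TAA stop
    assert classify_productive("TGTGCAGGGTT") == (False, False, False)  # 11 nt
    # a stop straddling codons in another frame is not frame-0
    assert classify_productive("TTGACC") == (True, False, True)
    with pytest.raises(ValueError):
        classify_productive("")


def test_assign_segment_unique_call(mini_ref):
    read = _read_seq(V1_SEQ, "GGCACC")
    call, aln, flags, use_rc = assign_segment(read, mini_ref.functional("V"))
    assert call == "TRGV1.1"
    assert aln.score == len(V1_SEQ) * 5
    assert flags == set() and use_rc is False


def test_assign_segment_grouped_call_in_locus_order(mini_ref):
    read = _read_seq(V2_SEQ, "GGCACC")
    call, aln, flags, use_rc = assign_segment(read, mini_ref.functional("V"))
    assert call == "TRGV2.1/2.2"
    assert flags == set()


def test_assign_segment_reverse_complement(mini_ref):
    read = revcomp(_read_seq(V1_SEQ, "GGCACC"))
    call, _, _, use_rc = assign_segment(read, mini_ref.functional("V"))
    assert call == "TRGV1.1"
    assert use_rc is True


def test_assign_segment_below_min_score(mini_ref):
    call, aln, flags, _ = assign_segment("ACGTACGTACGTACGT",
                                         mini_ref.functional("V"))
    assert call is None and aln is None and flags == {"no_v"}
    _, _, jflags, _ = assign_segment("ACGTACGTACGTACGT", mini_ref.functional("J"))
    assert jflags == {"no_j"}


def test_assign_segment_input_validation(mini_ref):
    with pytest.raises(ValueError):
        assign_segment("ACGT", [])
    with pytest.raises(ValueError):
        assign_segment("ACGT", mini_ref.segments)  # mixed types


def test_extract_junction_exact(mini_ref):
    insert = "GGCACC"
    read = _read_seq(V1_SEQ, insert)
    v = mini_ref["TRGV1.1"]
    j = mini_ref["TRGJ1"]
    v_aln = smith_waterman(read, v.sequence)
    j_aln = smith_waterman(read, j.sequence)
    junction = extract_junction(read, v, j, v_aln, j_aln)
    # anchor-inclusive: V tail from the Cys codon + insert + J head through Phe
    assert junction == V1_SEQ[30:] + insert + J1_SEQ[:15]
    assert junction.startswith("TGT") and junction.endswith("TTT")


def test_extract_junction_anchor_outside_span_returns_none(mini_ref):
    # read containing only the first half of V: the anchor never aligns
    read = V1_SEQ[:20] + J1_SEQ + C_SEQ
    v = mini_ref["TRGV1.1"]
    j = mini_ref["TRGJ1"]
    v_aln = smith_waterman(read, v.sequence)
    j_aln = smith_waterman(read, j.sequence)
    assert extract_junction(read, v, j, v_aln, j_aln) is None


def test_annotate_partitions_and_flags(mini_ref):
    reads = {
        "s1": [
            ReadRecord("ok", _read_seq(V1_SEQ, "GGCACC")),
            ReadRecord("ambig", _read_seq(V2_SEQ, "GGCACC")),
            ReadRecord("junk", "ACGTACGTACGTACGTACGTACGT"),
            ReadRecord("noj", V1_SEQ + "GG" + "ACGTACGTACGTAC"),
        ],
    }
    table, counts = annotate(reads, mini_ref)
    assert counts["total"] == 4
    assert counts["assigned"] == 1
    assert counts["ambiguous_v_excluded"] == 1
    assert counts["no_v"] == 1
    assert counts["no_j"] == 1
    assert sum(v for k, v in counts.items() if k != "total") == counts["total"]
    row = table.set_index("sequence_id").loc["ambig"]
    assert row["v_call"] == "TRGV2.1/2.2"
    assert "ambiguous_v_excluded" in row["flags"]


def test_annotate_retained_group_is_assigned(mini_ref):
    cfg = AnnotateConfig(retained_groups=("TRGV2.1/2.2",))
    reads = {"s1": [ReadRecord("r", _read_seq(V2_SEQ, "GGCACC"))]}
    table, counts = annotate(reads, mini_ref, cfg)
    assert counts["assigned"] == 1
    assert "ambiguous_v_retained" in table.loc[0, "flags"]
    assert table.loc[0, "junction"] == V2_SEQ[30:] + "GGCACC" + J1_SEQ[:15]


def test_annotate_copies_sample_metadata(mini_ref):
    meta = pd.DataFrame({"sample_id": ["s1"], "bird_id": ["b9"],
                         "tissue": ["thymus"], "line": ["L"]}).set_index("sample_id")
    reads = {"s1": [ReadRecord("r", _read_seq(V1_SEQ, "GGCACC"))]}
    table, _ = annotate(reads, mini_ref, sample_metadata=meta)
    assert table.loc[0, ["bird_id", "tissue", "line"]].tolist() == \
        ["b9", "thymus", "L"]


def test_annotate_recovers_simulated_truth(small_sim):
    airr = small_sim["airr"].set_index("sequence_id")
    truth = small_sim["truth_reads"].set_index("read_id")
    merged = airr.join(truth, rsuffix="_truth")
    assert len(merged) == len(truth)
    assert (merged["v_call"] == merged["v_group"]).all()
    assert (merged["j_call"] == merged["j_id"]).all()
    assert (merged["junction"] == merged["junction_nt"]).all()
    assert small_sim["summary"]["no_v"] == 0
    assert small_sim["summary"]["no_junction"] == 0
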