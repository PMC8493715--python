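"""Ground-truthed TCR-gamma repertoire and read simulator.

Emulates the structure of the study data that the pipeline assumes: several
birds per line, several tissues per bird, strongly biased per-TRGV usage
(one dominant V gene, as seen in every chicken tissue), V–J junctions built
from trimmed germline ends plus non-templated N insertions, public clones
planted at nucleotide identity across a chosen fraction of birds, clonal
expansion, and per-base substitution sequencing error. Every emitted read
carries a truth-table row, so demultiplexing, annotation and every
downstream statistic can be checked against known ground truth.

Reads follow the 5'RACE amplicon layout: universal adapter, sample barcode,
the V region, the junction, the retained J tail and a fragment of C. The
default configuration mirrors the study conditions used throughout the test
suite: one line of 8 birds, 5 tissues, 5000 reads per bird x tissue sample,
dominant-gene usage of 0.35, and error-free reads (error is opt-in so that
junction-recovery oracles are exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import format_group
from .demux import ReadRecord, SampleSheet
from .reference import LocusAnnotation, bundled_reference

__all__ = [
    "PublicCloneSpec",
    "SimulationConfig",
    "default_v_usage",
    "expected_groups",
    "simulate_repertoire",
    "simulate_reads",
]

UPA_ADAPTER = "AAGCAGTGGTATCAACGCAGAG"  # synthetic universal 5'RACE adapter
BARCODE_LENGTH = 8
C_FRAGMENT = 30
BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = ["sample_id", "line", "bird_id", "tissue", "v_id", "v_group",
                 "j_id", "junction_nt", "clone_id", "is_public", "read_count"]


@dataclass(frozen=True)
class PublicCloneSpec:
    """A clone planted (junction-nucleotide-identical) across birds."""

    v_id: str
    penetrance: float
    expansion_factor: float = 5.0
    junction_nt: str | None = None
    j_id: str | None = None

    def __post_init__(self):
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")


@dataclass
class SimulationConfig:
    """All knobs of the generator; see module docstring for the rationale
    behind the defaults."""

    seed: int = 0
    lines: tuple[str, ...] = ("ISA_Brown",)
    birds_per_line: int | Mapping[str, int] = 8
    tissues: tuple[str, ...] = ("thymus", "spleen", "jejunum", "caecum", "colon")
    reads_per_sample: int = 5000
    clones_per_bird: int = 150
    v_usage: Mapping[str, float] | None = None  # None -> default_v_usage
    j_usage: Mapping[str, float] | None = None  # None -> uniform
    trim_v_p: float = 1 / 3  # geometric, mean 2 nt trimmed from the V tail
    trim_j_p: float = 1 / 3
    n_insert_mean: float = 4.0  # Poisson N-insertion length
    insert_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    clone_size_sigma: float = 1.0  # lognormal clone-size dispersion
    public_pool: tuple[PublicCloneSpec, ...] = ()
    error_rate: float = 0.0
    reverse_fraction: float = 0.0  # fraction of reads emitted reverse-complemented

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if abs(sum(self.insert_base_probs) - 1) > 1e-9:
            raise ValueError("insert_base_probs must sum to 1")
        for m in (self.v_usage, self.j_usage):
            if m is not None and abs(sum(m.values()) - 1) > 1e-9:
                raise ValueError("usage probabilities must sum to 1")

    def n_birds(self, line: str) -> int:
        if isinstance(self.birds_per_line, Mapping):
            return self.birds_per_line[line]
        return self.birds_per_line


def expected_groups(reference: LocusAnnotation) -> dict[str, str]:
    """Map each functional V id to its expected assignment-level group id.

    Germline-identical V segments cannot be separated by alignment and are
    always reported as a grouped call; all other segments map to themselves.
    """
    by_seq: dict[str, list] = {}
    for s in reference.functional("V"):
        by_seq.setdefault(s.sequence, []).append(s)
    out = {}
    for members in by_seq.values():
        members.sort(key=lambda s: s.locus_start)
        gid = members[0].id if len(members) == 1 else format_group([m.id for m in members])
        for m in members:
            out[m.id] = gid
    return out


def default_v_usage(reference: LocusAnnotation, dominant: str = "TRGV3.3",
                    dominant_p: float = 0.35) -> dict[str, float]:
    """Study-like usage over expressed V genes: one dominant gene (default
    0.35), elevated TRGV1.3 / TRGV2.20, the rest uniform."""
    expressed = [s.id for s in reference.v_segments
                 if s.functional_status == "functional"]
    elevated = {dominant: dominant_p}
    for vid, p in (("TRGV1.3", 0.12), ("TRGV2.20", 0.10)):
        if vid in expressed and vid != dominant:
            elevated[vid] = p
    rest = [v for v in expressed if v not in elevated]
    remaining = 1.0 - sum(elevated.values())
    usage = dict(elevated)
    for v in rest:
        usage[v] = remaining / len(rest)
    return usage


def make_junction(reference: LocusAnnotation, v_id: str, j_id: str,
                  insert: str = "", trim_v: int = 0, trim_j: int = 0) -> str:
    """A structurally valid junction for explicit clone planting: V tail from
    the anchor (minus ``trim_v``) + ``insert`` + J head through the anchor
    codon (minus ``trim_j`` from the 5' end)."""
    v_seg, j_seg = reference[v_id], reference[j_id]
    v_part = v_seg.sequence[v_seg.junction_anchor_offset: len(v_seg.sequence) - trim_v
                            if trim_v else None]
    j_part = j_seg.sequence[trim_j: j_seg.junction_anchor_offset + 3]
    return v_part + insert + j_part


def _draw_junction(rng, v_seg, j_seg, cfg: SimulationConfig) -> str:
    """Junction = V tail from the anchor (minus trimming) + N insert + J head
    up to and including the anchor codon. Anchors are always preserved."""
    v_tail_max = len(v_seg.sequence) - v_seg.junction_anchor_offset - 3
    j_head_max = j_seg.junction_anchor_offset
    trim_v = min(int(rng.geometric(cfg.trim_v_p) - 1), v_tail_max)
    trim_j = min(int(rng.geometric(cfg.trim_j_p) - 1), j_head_max)
    nins = int(rng.poisson(cfg.n_insert_mean))
    insert = "".join(rng.choice(BASES, size=nins, p=np.asarray(cfg.insert_base_probs)))
    v_part = v_seg.sequence[v_seg.junction_anchor_offset: len(v_seg.sequence) - trim_v]
    j_part = j_seg.sequence[trim_j: j_seg.junction_anchor_offset + 3]
    return v_part + insert + j_part


def _make_barcodes(n: int, rng) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= 3."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(BASES, size=BARCODE_LENGTH))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 3 for bc in out):
            out.append(cand)
    return out


def simulate_repertoire(
    config: SimulationConfig,
    reference: LocusAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-bird clone repertoires and per-sample read counts.

    Returns ``(truth_table, clone_defs)``. ``truth_table`` has one row per
    (sample, clone) with its read count; counts per sample sum exactly to
    ``reads_per_sample``. ``clone_defs`` describes each distinct clone.
    Public-pool clones are planted in ``ceil(penetrance * n_birds)`` birds
    of every line with clone weight scaled by ``expansion_factor``.
    """
    reference = reference or bundled_reference()
    rng = np.random.default_rng(config.seed)
    v_usage = dict(config.v_usage) if config.v_usage else default_v_usage(reference)
    for vid in v_usage:
        if vid not in reference:
            raise ValueError(f"v_usage id {vid!r} not in reference")
        if reference[vid].junction_anchor_offset is None:
            raise ValueError(f"v_usage id {vid!r} has no junction anchor")
    j_ids = [s.id for s in reference.functional("J")]
    j_usage = dict(config.j_usage) if config.j_usage else {j: 1 / len(j_ids) for j in j_ids}
    groups = expected_groups(reference)

    v_ids = sorted(v_usage)
    v_probs = np.array([v_usage[v] for v in v_ids])
    jj_ids = sorted(j_usage)
    j_probs = np.array([j_usage[j] for j in jj_ids])

    # public clone definitions are drawn once, shared across lines and birds
    public_defs = []
    for k, spec in enumerate(config.public_pool):
        v_seg = reference[spec.v_id]
        j_id = spec.j_id or jj_ids[rng.choice(len(jj_ids), p=j_probs)]
        junction = spec.junction_nt or _draw_junction(rng, v_seg, reference[j_id], config)
        public_defs.append({
            "clone_id": f"pub{k}", "v_id": spec.v_id, "v_group": groups.get(spec.v_id, spec.v_id),
            "j_id": j_id, "junction_nt": junction, "is_public": True,
            "penetrance": spec.penetrance, "expansion_factor": spec.expansion_factor,
        })

    clone_rows = list(public_defs)
    truth_rows = []
    mean_private_weight = math.exp(config.clone_size_sigma ** 2 / 2)
    for line in config.lines:
        n_birds = config.n_birds(line)
        # which birds carry each public clone
        carriers = {}
        for pd_ in public_defs:
            k = math.ceil(pd_["penetrance"] * n_birds)
            carriers[pd_["clone_id"]] = set(rng.choice(n_birds, size=k, replace=False))
        for b in range(n_birds):
            bird_id = f"{line}_bird{b + 1}"
            clones = []
            for i in range(config.clones_per_bird):
                v_id = v_ids[rng.choice(len(v_ids), p=v_probs)]
                j_id = jj_ids[rng.choice(len(jj_ids), p=j_probs)]
                junction = _draw_junction(rng, reference[v_id], reference[j_id], config)
                cid = f"{bird_id}_c{i}"
                clone_rows.append({
                    "clone_id": cid, "v_id": v_id, "v_group": groups.get(v_id, v_id),
                    "j_id": j_id, "junction_nt": junction, "is_public": False,
                    "penetrance": 1 / n_birds, "expansion_factor": 1.0,
                })
                clones.append((cid, v_id, j_id, junction, False,
                               float(rng.lognormal(0, config.clone_size_sigma))))
            for pd_ in public_defs:
                if b in carriers[pd_["clone_id"]]:
                    clones.append((pd_["clone_id"], pd_["v_id"], pd_["j_id"],
                                   pd_["junction_nt"], True,
                                   mean_private_weight * pd_["expansion_factor"]))
            weights = np.array([c[5] for c in clones])
            probs = weights / weights.sum()
            for tissue in config.tissues:
                counts = rng.multinomial(config.reads_per_sample, probs)
                sample_id = f"{line}_b{b + 1}_{tissue}"
                for (cid, v_id, j_id, junction, is_pub, _), cnt in zip(clones, counts):
                    if cnt == 0:
                        continue
                    truth_rows.append({
                        "sample_id": sample_id, "line": line, "bird_id": bird_id,
                        "tissue": tissue, "v_id": v_id,
                        "v_group": groups.get(v_id, v_id), "j_id": j_id,
                        "junction_nt": junction, "clone_id": cid,
                        "is_public": is_pub, "read_count": int(cnt),
                    })
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    clone_defs = pd.DataFrame(clone_rows)
    return truth, clone_defs


def simulate_reads(
    truth: pd.DataFrame,
    reference: LocusAnnotation | None = None,
    config: SimulationConfig | None = None,
) -> tuple[list[ReadRecord], SampleSheet, pd.DataFrame]:
    """Assemble 5'RACE-style reads for every truth row.

    Returns ``(reads, sample_sheet, per_read_truth)``. With
    ``error_rate == 0`` every read contains its germline V and J segments
    and planted junction exactly, so the demultiplex → annotate pipeline
    recovers sample, V, J and junction for every read whose V group is
    unambiguous. Same seed, same truth → byte-identical output.
    """
    reference = reference or bundled_reference()
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)  # independent of repertoire draws
    c_seq = reference.of_type("C")[0].sequence[:C_FRAGMENT]

    samples = sorted(truth["sample_id"].unique())
    barcodes = _make_barcodes(len(samples), rng)
    bc_of = dict(zip(samples, barcodes))
    meta = (truth[["sample_id", "line", "bird_id", "tissue"]]
            .drop_duplicates().set_index("sample_id"))
    sheet_rows = pd.DataFrame({
        "sample_id": samples,
        "barcode": [bc_of[s] for s in samples],
        "bird_id": [meta.loc[s, "bird_id"] for s in samples],
        "tissue": [meta.loc[s, "tissue"] for s in samples],
        "line": [meta.loc[s, "line"] for s in samples],
    })
    sheet = SampleSheet(sheet_rows, barcode_offset=len(UPA_ADAPTER))

    reads: list[ReadRecord] = []
    truth_reads = []
    n = 0
    for row in truth.itertuples(index=False):
        v_seg = reference[row.v_id]
        j_seg = reference[row.j_id]
        body = (UPA_ADAPTER + bc_of[row.sample_id]
                + v_seg.sequence[:v_seg.junction_anchor_offset]
                + row.junction_nt
                + j_seg.sequence[j_seg.junction_anchor_offset + 3:]
                + c_seq)
        for _ in range(row.read_count):
            seq = body
            if config.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hit = rng.random(arr.size) < config.error_rate
                if hit.any():
                    chars = list(seq)
                    for i in np.nonzero(hit)[0]:
                        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
                    seq = "".join(chars)
            rid = f"read{n:07d}"
            n += 1
            rec = ReadRecord(rid, seq)
            if config.reverse_fraction > 0 and rng.random() < config.reverse_fraction:
                rec = rec.revcomp()
            reads.append(rec)
            truth_reads.append({
                "read_id": rid, "sample_id": row.sample_id, "line": row.line,
                "bird_id": row.bird_id, "tissue": row.tissue, "v_id": row.v_id,
                "v_group": row.v_group, "j_id": row.j_id,
                "junction_nt": row.junction_nt, "clone_id": row.clone_id,
                "is_public": row.is_public,
            })
    return reads, sheet, pd.DataFrame(truth_reads)
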