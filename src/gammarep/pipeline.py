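"""End-to-end orchestration: demultiplex → annotate → tables → statistics.

A single :class:`RunConfig` (loadable from YAML) drives all stages; every
output file is checksummed into a run manifest so that re-running with the
same inputs, config and seed reproduces identical checksums. Figure-level
constants (publicity thresholds 0.6/0.8/1.0, coverage target 0.1, 500
bootstrap replicates, down-sampling to 5 birds) are config defaults, not
hard-coded in the stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as div
from .annotate import AnnotateConfig, annotate
from .demux import SampleSheet, demultiplex, read_fastq
from .publicity import compute_publicity, cross_line_sharing, public_fraction_by_v
from .reference import LocusAnnotation, bundled_reference, load_reference
from .tables import build_clonotype_table, usage_proportions

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    reads_fastq: str
    sample_sheet: str
    out_dir: str
    reference_fasta: str | None = None
    reference_metadata: str | None = None
    seed: int = 0
    barcode_offset: int = 22
    max_mismatches: int = 0
    filter: str = "in_frame"
    coverage_target: float = 0.1
    hill_orders: tuple[float, ...] = (0, 1, 2)
    publicity_thresholds: tuple[float, float, float] = (0.6, 0.8, 1.0)
    bootstrap_replicates: int = 500
    downsample_birds_to: int = 5
    min_score: int = 60

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.reads_fastq, self.sample_sheet,
                  self.reference_fasta, self.reference_metadata):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_ref(cfg: RunConfig) -> LocusAnnotation:
    if cfg.reference_fasta and cfg.reference_metadata:
        return load_reference(cfg.reference_fasta, cfg.reference_metadata,
                              provenance="user reference")
    return bundled_reference()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    Stage order: demultiplex → annotate → clonotype table → usage →
    diversity → publicity (per line with >= 2 birds; cross-line sharing
    when two lines are present). Empty inputs produce empty outputs and a
    warning, not an error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = _load_ref(config)
    sheet = SampleSheet.from_tsv(config.sample_sheet, barcode_offset=config.barcode_offset)

    outputs: dict[str, Path] = {}

    streams, counts = demultiplex(read_fastq(config.reads_fastq), sheet,
                                  config.max_mismatches)
    p = out / "demux_counts.json"
    p.write_text(json.dumps(counts, indent=2, sort_keys=True))
    outputs["demux_counts"] = p

    streams.pop("undetermined", None)
    airr, summary = annotate(streams, reference,
                             AnnotateConfig(min_score=config.min_score),
                             sample_metadata=sheet.metadata())
    p = out / "rearrangements.tsv"
    airr.to_csv(p, sep="\t", index=False)
    outputs["rearrangements"] = p
    p = out / "annotate_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["annotate_summary"] = p

    table = build_clonotype_table(airr, filter=config.filter)
    p = out / "clonotypes.tsv"
    table.to_csv(p, sep="\t", index=False)
    outputs["clonotypes"] = p

    if table.empty:
        warnings.warn("no clonotypes passed filtering; downstream outputs empty")
        usage = pd.DataFrame()
        div_rows = pd.DataFrame()
    else:
        usage = usage_proportions(table, replicates=config.bootstrap_replicates,
                                  seed=config.seed)
        rows = []
        for unit, x in div.abundances_from_table(table).items():
            for q in config.hill_orders:
                est = div.hill_at_coverage(x, config.coverage_target, q)
                rows.append({"unit": "/".join(map(str, unit)), "q": q, "m": est.m,
                             "coverage": est.coverage, "estimate": est.value,
                             "method": est.method})
        div_rows = pd.DataFrame(rows)
    p = out / "usage.tsv"
    usage.to_csv(p, sep="\t", index=False)
    outputs["usage"] = p
    p = out / "diversity.tsv"
    div_rows.to_csv(p, sep="\t", index=False)
    outputs["diversity"] = p

    pub_frames = []
    records_by_line = {}
    if not table.empty:
        for line, sub in table.groupby("line"):
            if sub["bird_id"].nunique() < 2:
                warnings.warn(f"line {line!r} has < 2 birds; publicity skipped")
                continue
            recs = compute_publicity(table, line, config.publicity_thresholds)
            records_by_line[line] = recs
            frac = public_fraction_by_v(recs, table, line)
            frac.insert(0, "line", line)
            pub_frames.append(frac)
    pub = pd.concat(pub_frames, ignore_index=True) if pub_frames else pd.DataFrame()
    p = out / "publicity.tsv"
    pub.to_csv(p, sep="\t", index=False)
    outputs["publicity"] = p

    if len(records_by_line) == 2:
        (la, ra), (lb, rb) = sorted(records_by_line.items())
        sharing = {
            la: {"weighted": cross_line_sharing(ra, rb, "weighted", table, la),
                 "unweighted": cross_line_sharing(ra, rb, "unweighted")},
            lb: {"weighted": cross_line_sharing(rb, ra, "weighted", table, lb),
                 "unweighted": cross_line_sharing(rb, ra, "unweighted")},
        }
        p = out / "sharing.json"
        p.write_text(json.dumps(sharing, indent=2, sort_keys=True))
        outputs["sharing"] = p

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "read_counts": counts,
        "annotate_summary": summary,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
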