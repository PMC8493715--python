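"""Demultiplexing of pooled 5'RACE amplicon reads by barcoded primer tag.

Each sample's gene-specific primer carries a short index barcode at a fixed
offset in the read. A read is assigned to the unique barcode matching within
``max_mismatches`` at that offset, checked on the read as given and on its
reverse complement; when the reverse complement matches, the emitted read is
re-oriented so the barcode lies on the given strand. Reads matching zero or
two or more barcodes, or too short to contain the barcode, go to the
``undetermined`` stream. No read is dropped or duplicated.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .align import revcomp

__all__ = ["ReadRecord", "SampleSheet", "demultiplex", "read_fastq", "write_fastq"]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (quality optional)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length differs from sequence length")

    def revcomp(self) -> "ReadRecord":
        q = self.quality[::-1] if self.quality is not None else None
        return ReadRecord(self.read_id, revcomp(self.sequence), q)


@dataclass
class SampleSheet:
    """Barcode → sample mapping with bird/tissue/line metadata."""

    rows: pd.DataFrame  # columns: sample_id, barcode, bird_id, tissue, line
    barcode_offset: int = 0

    REQUIRED = ("sample_id", "barcode", "bird_id", "tissue", "line")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        self.rows = self.rows.astype({c: str for c in self.REQUIRED})
        barcodes = self.rows["barcode"]
        if barcodes.duplicated().any():
            raise ValueError("duplicate barcodes in sample sheet")
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")
        if len(set(barcodes.str.len())) > 1:
            raise ValueError("barcodes must all have the same length")
        if (self.rows["tissue"] == "").any() or (self.rows["line"] == "").any():
            raise ValueError("tissue and line must be non-empty")

    @property
    def barcode_length(self) -> int:
        return len(self.rows["barcode"].iloc[0])

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return dict(zip(self.rows["barcode"], self.rows["sample_id"]))

    def metadata(self) -> pd.DataFrame:
        return self.rows.set_index("sample_id")

    @classmethod
    def from_tsv(cls, path, barcode_offset: int = 0) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str), barcode_offset)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _match_barcode(segment: str, barcodes: dict[str, str], max_mm: int) -> str | None:
    """Unique sample whose barcode is within max_mm of segment, else None."""
    if max_mm == 0:
        return barcodes.get(segment)
    hits = []
    best = max_mm + 1
    for bc, sample in barcodes.items():
        mm = sum(a != b for a, b in zip(segment, bc))
        if mm < best:
            best = mm
            hits = [sample]
        elif mm == best:
            hits.append(sample)
    return hits[0] if best <= max_mm and len(hits) == 1 else None


def demultiplex(
    reads: Iterable[ReadRecord],
    sheet: SampleSheet,
    max_mismatches: int = 0,
) -> tuple[dict[str, list[ReadRecord]], dict[str, int]]:
    """Split reads by barcode; returns (streams by sample + undetermined, counts).

    The sum of all output counts equals the input count (read conservation).
    """
    barcodes = sheet.barcode_to_sample
    off = sheet.barcode_offset
    blen = sheet.barcode_length
    out: dict[str, list[ReadRecord]] = {s: [] for s in barcodes.values()}
    out[UNDETERMINED] = []
    for read in reads:
        if len(read.sequence) < off + blen:
            out[UNDETERMINED].append(read)
            continue
        fwd = _match_barcode(read.sequence[off:off + blen], barcodes, max_mismatches)
        rc = read.revcomp()
        rev = _match_barcode(rc.sequence[off:off + blen], barcodes, max_mismatches)
        if fwd is not None and (rev is None or rev == fwd):
            out[fwd].append(read)
        elif rev is not None and fwd is None:
            out[rev].append(rc)
        else:
            out[UNDETERMINED].append(read)
    counts = {s: len(v) for s, v in out.items()}
    return out, counts


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq), qual)


def write_fastq(path, reads: Iterable[ReadRecord]) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def demultiplex_files(
    fastq_path,
    sheet: SampleSheet,
    out_dir,
    max_mismatches: int = 0,
) -> dict[str, int]:
    """File-level wrapper: FASTQ in, per-sample FASTQ + counts JSON out."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams, counts = demultiplex(read_fastq(fastq_path), sheet, max_mismatches)
    for sample, recs in streams.items():
        write_fastq(out_dir / f"{sample}.fastq", recs)
    with open(out_dir / "demux_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    return counts
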