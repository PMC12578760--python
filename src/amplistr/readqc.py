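"""Read length/quality filtering for amplicon long reads.

Filters mirror the conventional nanopore amplicon workflow: keep reads whose
length falls inside a window bracketing the expected amplicon size (default
4,000-6,000 bases, inclusive) and whose mean quality exceeds a Phred floor
(default Q10, strict).  Mean quality is computed in error-probability space:
``-10*log10(mean per-base error probability)``, the convention of the
standard long-read filtering tools, which down-weights reads with runs of
very poor bases more than an arithmetic mean of Phred scores would.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .simulate import SimRead, write_fastq

__all__ = ["QcThresholds", "QcSummary", "mean_quality", "filter_reads", "read_fastq"]


@dataclass(frozen=True)
class QcThresholds:
    min_len: int = 4000
    max_len: int = 6000
    min_mean_q: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError(f"need 0 < min_len <= max_len, got {self.min_len}..{self.max_len}")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be non-negative")


@dataclass
class QcSummary:
    total: int = 0
    kept: int = 0
    rejected_length: int = 0
    rejected_quality: int = 0
    malformed: int = 0
    mean_length: float = float("nan")
    mean_mean_q: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def mean_quality(quality: str) -> float:
    """Phred-scaled mean error probability of a Phred+33 quality string."""
    if not quality:
        raise ValueError("quality string is empty")
    phred = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.float64) - 33.0
    if phred.min() < 0:
        raise ValueError("quality string contains characters below Phred+33 zero")
    mean_err = np.mean(10.0 ** (-phred / 10.0))
    return -10.0 * math.log10(mean_err)


def filter_reads(
    reads: list[SimRead], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[SimRead], QcSummary]:
    """Apply the length window (inclusive) and strict mean-quality floor.

    Records whose sequence and quality lengths disagree, or whose quality
    cannot be interpreted, are counted as malformed and skipped.
    """
    summary = QcSummary(total=len(reads))
    kept: list[SimRead] = []
    lengths: list[int] = []
    quals: list[float] = []
    for read in reads:
        if not read.sequence or len(read.sequence) != len(read.quality):
            summary.malformed += 1
            continue
        try:
            q = mean_quality(read.quality)
        except ValueError:
            summary.malformed += 1
            continue
        lengths.append(len(read.sequence))
        quals.append(q)
        if not thresholds.min_len <= len(read.sequence) <= thresholds.max_len:
            summary.rejected_length += 1
        elif not q > thresholds.min_mean_q:
            summary.rejected_quality += 1
        else:
            kept.append(read)
    summary.kept = len(kept)
    if lengths:
        summary.mean_length = float(np.mean(lengths))
        summary.mean_mean_q = float(np.mean(quals))
    return kept, summary


def read_fastq(path: str | Path) -> list[SimRead]:
    """Parse a (possibly gzipped) Phred+33 FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads: list[SimRead] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(SimRead(rec.id, str(rec.seq), qual))
    return reads


def qc_file(
    in_path: str | Path,
    out_path: str | Path | None,
    thresholds: QcThresholds = QcThresholds(),
) -> QcSummary:
    """Filter a FASTQ file on disk; convenience wrapper for the CLI."""
    reads = read_fastq(in_path)
    kept, summary = filter_reads(reads, thresholds)
    if out_path is not None:
        write_fastq(kept, out_path)
    return summary
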