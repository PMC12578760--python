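"""Synthetic nanopore-like amplicon reads for a diploid repeat genotype.

The generator emulates the features of a long-range-PCR / nanopore run that
a repeat caller must tolerate: an indel-dominant per-base error channel,
per-read mosaic jitter of the repeat count (somatic length variation, not
sequencing noise), PCR length bias favouring the shorter allele, a small
fraction of artefact reads carrying fewer than five repeat units, and random
read orientation.  Every read is emitted together with a truth record so
that downstream stages can be scored exactly.

All randomness flows from a single integer seed; the same config produces
byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus import RepeatLocus, build_amplicon

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimRead",
    "choose_allele",
    "corrupt",
    "simulate_sample",
    "write_fastq",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")

#: Reads counting fewer than this many units are treated as PCR/counting
#: artefacts; the simulator plants them and the caller must shed them.
ARTEFACT_UNIT_CEILING = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic sample generator.

    Error-rate defaults are indel-dominant (insertion + deletion exceeding
    substitution), mirroring the nanopore error profile; ``mosaic_sd`` is the
    standard deviation of the per-read unit-count jitter as a fraction of the
    allele's size; ``pcr_lambda`` is the per-base length-bias coefficient of
    preferential short-allele amplification.
    """

    genotype: tuple[int, int]
    n_reads: int = 200
    sub_rate: float = 0.02
    ins_rate: float = 0.03
    del_rate: float = 0.04
    mosaic_sd: float = 0.03
    pcr_lambda: float = 0.0
    artefact_fraction: float = 0.02
    mean_q: float = 14.0
    q_sd: float = 3.0
    seed: int = 0
    # Per-allele SNP base per site: rsid -> (base on allele 1, base on allele 2).
    snp_haplotypes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1, n2 = self.genotype
        if n1 < 0 or n1 > n2:
            raise ValueError(f"genotype must satisfy 0 <= n1 <= n2, got {self.genotype}")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {rate}")
        if not 0.0 <= self.artefact_fraction <= 0.5:
            raise ValueError(f"artefact_fraction must lie in [0, 0.5], got {self.artefact_fraction}")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.mosaic_sd < 0:
            raise ValueError("mosaic_sd must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    source_allele: int  # 1 or 2
    true_units: int  # post-jitter
    strand: str  # "+" or "-"
    is_artefact: bool


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33


def choose_allele(config: SimulationConfig, locus: RepeatLocus, rng: np.random.Generator) -> int:
    """Pick the source allele (1 or 2) of one read.

    The probability of each allele is proportional to
    ``exp(-pcr_lambda * amplicon_length)``, so a positive ``pcr_lambda``
    favours the shorter allele; at 0 the split is even.
    """
    n1, n2 = config.genotype
    flank = len(locus.left_flank) + len(locus.right_flank)
    unit = len(locus.unit)
    w1 = math.exp(-config.pcr_lambda * (flank + unit * n1))
    w2 = math.exp(-config.pcr_lambda * (flank + unit * n2))
    return 1 if rng.random() < w1 / (w1 + w2) else 2


def corrupt(
    seq: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """Push a sequence through the i.i.d. per-base error channel.

    Per input base: deleted with ``del_rate``; otherwise emitted, substituted
    with ``sub_rate``; independently, a random base is inserted after it with
    ``ins_rate``.  Qualities are drawn from a Gaussian around ``mean_q``,
    truncated to [2, 40].  Returns (read sequence, Phred+33 quality string)
    of equal length.
    """
    if not seq:
        raise ValueError("cannot corrupt an empty sequence")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    keep = rng.random(n) >= config.del_rate
    sub = rng.random(n) < config.sub_rate
    ins = rng.random(n) < config.ins_rate
    codes = np.searchsorted(_BASES, arr)  # ACGT are sorted bytes
    codes = np.where(sub, (codes + rng.integers(1, 4, size=n)) % 4, codes)
    ins_codes = rng.integers(0, 4, size=n)
    slots = np.empty(2 * n, dtype=np.uint8)
    slots[0::2] = _BASES[codes]
    slots[1::2] = _BASES[ins_codes]
    mask = np.empty(2 * n, dtype=bool)
    mask[0::2] = keep
    mask[1::2] = ins
    out = slots[mask]
    quals = np.clip(np.rint(rng.normal(config.mean_q, config.q_sd, size=out.size)), 2, 40)
    qual_bytes = (quals.astype(np.uint8) + 33).tobytes()
    return out.tobytes().decode("ascii"), qual_bytes.decode("ascii")


def simulate_sample(
    locus: RepeatLocus, config: SimulationConfig
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Generate one sample's reads and matching truth labels.

    For each read: pick a source allele (PCR-bias-weighted), jitter its unit
    count with rounded Normal(0, mosaic_sd * n) mosaicism, build the
    haplotype amplicon (per-allele SNP bases applied), reverse-complement
    with probability 0.5, and corrupt.  A configured fraction of reads are
    replaced by artefacts carrying 0-4 repeat units.
    """
    rng = np.random.default_rng(config.seed)
    sites = {s.rsid: s for s in locus.snp_sites}
    for rsid in config.snp_haplotypes:
        if rsid not in sites:
            raise KeyError(f"snp_haplotypes names unknown site {rsid!r}")
    reads: list[SimRead] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        read_id = f"sim_s{config.seed}_r{i:05d}"
        allele = choose_allele(config, locus, rng)
        is_artefact = rng.random() < config.artefact_fraction
        if is_artefact:
            true_units = int(rng.integers(0, ARTEFACT_UNIT_CEILING))
        else:
            n = config.genotype[allele - 1]
            jitter = int(round(rng.normal(0.0, config.mosaic_sd * n)))
            true_units = max(0, n + jitter)
        snp_bases = {
            rsid: pair[allele - 1] for rsid, pair in config.snp_haplotypes.items()
        }
        template = build_amplicon(locus, true_units, snp_bases=snp_bases or None)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = reverse_complement(template)
        seq, qual = corrupt(template, config, rng)
        reads.append(SimRead(read_id, seq, qual))
        truths.append(TruthRecord(read_id, allele, true_units, strand, is_artefact))
    return reads, truths


# -- output ----------------------------------------------------------------


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ; gzip-compressed if the path ends .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "source_allele": [t.source_allele for t in truths],
            "true_units": [t.true_units for t in truths],
            "strand": [t.strand for t in truths],
            "is_artefact": [int(t.is_artefact) for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)
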