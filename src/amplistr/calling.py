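"""Diploid allele calling from per-read repeat-count histograms.

The procedure mirrors the histogram-based sizing convention for repeat
amplicon data:

1. discard uncountable reads and reads counting fewer than 5 units (a
   counting-artefact floor observed across samples);
2. smooth the repeat-count histogram with a short centred moving average
   and take up to two local maxima as provisional allele modes, merging
   peaks closer than a minimum separation;
3. gate every reported allele on more than 10 supporting reads;
4. when only one mode is found, attempt to split it by a linked SNP: if the
   reads partition into two well-supported groups with different modal
   sizes, the sample is heterozygous for two similar-sized alleles;
5. classify each allele (normal < 35, intermediate 35-49 advisory,
   expanded >= 50) and flag broad or multi-peaked allele distributions as
   mosaic.

An expansion carrier is a sample with at least one allele of >= 50 units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import ARTEFACT_FLOOR, ReadObservation
from .locus import RepeatLocus

__all__ = [
    "CallerParams",
    "RepeatHistogram",
    "AlleleCall",
    "SampleGenotype",
    "build_histogram",
    "call_modes",
    "phase_and_refine",
    "classify_allele",
    "flag_mosaicism",
    "call_genotype",
    "NoCallError",
]

EXPANSION_THRESHOLD = 50
INTERMEDIATE_BAND = (35, 49)


class NoCallError(RuntimeError):
    """Raised when no allele mode survives the depth gate."""


@dataclass(frozen=True)
class CallerParams:
    #: Two modes closer than this many units are merged (the SNP-phasing
    #: path then tries to split them).
    min_separation: int = 8
    #: Width of the centred moving-average smoother (odd).
    smooth_window: int = 3
    #: An allele needs strictly more than this many supporting reads.
    depth_gate: int = 10
    #: Majority fraction required for a per-allele SNP consensus base.
    consensus_frac: float = 0.8
    artefact_floor: int = ARTEFACT_FLOOR


@dataclass
class RepeatHistogram:
    """Repeat-size frequency table after the artefact floor."""

    counts: dict[int, int]
    total_reads: int
    artefact_reads: int = 0
    uncountable_reads: int = 0

    def __post_init__(self) -> None:
        if any(size < ARTEFACT_FLOOR for size in self.counts):
            raise ValueError("histogram contains sizes below the artefact floor")
        if sum(self.counts.values()) != self.total_reads:
            raise ValueError("total_reads does not match the sum of counts")

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(self.counts)
        return pd.DataFrame(
            {"repeat_size": sizes, "n_reads": [self.counts[s] for s in sizes]}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Mode:
    size: int
    depth: int
    basin: tuple[int, ...]  # histogram sizes assigned to this mode


@dataclass(frozen=True)
class AlleleCall:
    size: int
    depth: int
    classification: str  # normal | intermediate | expanded
    mosaic_flag: bool = False
    phase_base: str | None = None


@dataclass
class SampleGenotype:
    sample_id: str
    alleles: tuple[AlleleCall, ...]  # sorted ascending by size
    zygosity: str  # heterozygous | homozygous | single-allele-low-confidence
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def expansion_carrier(self) -> bool:
        return any(a.size >= EXPANSION_THRESHOLD for a in self.alleles)

    @property
    def biallelic_expansion(self) -> bool:
        return (
            len(self.alleles) == 2
            and all(a.size >= EXPANSION_THRESHOLD for a in self.alleles)
            and self.zygosity != "single-allele-low-confidence"
        )


def build_histogram(
    observations: list[ReadObservation] | list[int | None],
    artefact_floor: int = ARTEFACT_FLOOR,
) -> RepeatHistogram:
    """Bin per-read counts at unit resolution, shedding artefacts.

    Accepts either ReadObservations or bare repeat counts (None meaning
    uncountable).  Counts below ``artefact_floor`` are excluded and tallied
    separately.
    """
    counts: Counter[int] = Counter()
    artefacts = uncountable = 0
    for item in observations:
        value = item.repeat_count if isinstance(item, ReadObservation) else item
        if value is None:
            uncountable += 1
        elif value < artefact_floor:
            artefacts += 1
        else:
            counts[int(value)] += 1
    return RepeatHistogram(
        counts=dict(counts),
        total_reads=sum(counts.values()),
        artefact_reads=artefacts,
        uncountable_reads=uncountable,
    )


def _smooth(raw: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or raw.size < window:
        return raw.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(raw.astype(float), kernel, mode="same")


def _mass_window(counts: dict[int, int], size: int, half_width: int = 2) -> int:
    return sum(counts.get(size + d, 0) for d in range(-half_width, half_width + 1))


def _refine_mode(counts: dict[int, int], basin: list[int]) -> int:
    """Raw argmax within a basin; ties to greater ±2-window mass, then smaller size."""
    best = max(
        basin,
        key=lambda s: (counts.get(s, 0), _mass_window(counts, s), -s),
    )
    return best


def call_modes(
    histogram: RepeatHistogram, params: CallerParams = CallerParams()
) -> list[Mode]:
    """Up to two allele modes from the smoothed histogram, depth-gated.

    Raises :class:`NoCallError` when every candidate fails the depth gate.
    """
    if not histogram.counts:
        raise NoCallError("empty histogram: no countable reads above the artefact floor")
    lo, hi = min(histogram.counts), max(histogram.counts)
    sizes = np.arange(lo, hi + 1)
    raw = np.array([histogram.counts.get(int(s), 0) for s in sizes])
    smooth = _smooth(raw, params.smooth_window)

    padded = np.concatenate(([-1.0], smooth, [-1.0]))
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] >= padded[2:]) & (raw + smooth > 0)
    candidates = [int(sizes[i]) for i in np.flatnonzero(is_peak)]
    # Collapse plateau runs of equal smoothed height into one representative.
    collapsed: list[int] = []
    for size in candidates:
        if collapsed and size - collapsed[-1] == 1:
            prev = collapsed[-1]
            if smooth[prev - lo] == smooth[size - lo]:
                keep = _refine_mode(histogram.counts, [prev, size])
                collapsed[-1] = keep
                continue
        collapsed.append(size)

    def rank_key(size: int) -> tuple:
        i = size - lo
        return (-smooth[i], -_mass_window(histogram.counts, size), size)

    selected: list[int] = []
    for size in sorted(collapsed, key=rank_key):
        if all(abs(size - other) >= params.min_separation for other in selected):
            selected.append(size)
        if len(selected) == 2:
            break

    while selected:
        basins: dict[int, list[int]] = {m: [] for m in selected}
        for s in histogram.counts:
            nearest = min(selected, key=lambda m: (abs(s - m), m))
            basins[nearest].append(s)
        modes = []
        for m in sorted(selected):
            basin = sorted(basins[m])
            depth = sum(histogram.counts[s] for s in basin)
            refined = _refine_mode(histogram.counts, basin) if basin else m
            modes.append(Mode(size=refined, depth=depth, basin=tuple(basin)))
        failing = [m for m in modes if m.depth <= params.depth_gate]
        if not failing:
            return sorted(modes, key=lambda m: m.size)
        # Drop the weakest failing mode and re-apportion its reads.
        weakest = min(failing, key=lambda m: (m.depth, m.size))
        selected = [s for s, m in zip(sorted(selected), modes) if m is not weakest]
    raise NoCallError(
        f"no mode exceeds the depth gate of {params.depth_gate} reads"
    )


def classify_allele(size: int) -> str:
    """normal (<35), intermediate (35-49, advisory), expanded (>=50)."""
    if size < ARTEFACT_FLOOR:
        raise ValueError(f"size {size} is below the artefact floor and cannot be classified")
    if size >= EXPANSION_THRESHOLD:
        return "expanded"
    if INTERMEDIATE_BAND[0] <= size <= INTERMEDIATE_BAND[1]:
        return "intermediate"
    return "normal"


def flag_mosaicism(
    histogram: RepeatHistogram, mode: Mode, half_width: int = 2
) -> bool:
    """Broad or multi-peaked allele distributions are flagged as mosaic.

    True when fewer than half of the mode's assigned reads sit within
    ±``half_width`` units of the modal size, or when the basin contains a
    separate raw local maximum of at least 30% of the modal height.
    """
    if mode.depth == 0:
        return False
    near = sum(
        histogram.counts.get(s, 0)
        for s in mode.basin
        if abs(s - mode.size) <= half_width
    )
    if near / mode.depth < 0.5:
        return True
    modal_height = histogram.counts.get(mode.size, 0)
    for s in mode.basin:
        if abs(s - mode.size) <= half_width:
            continue
        h = histogram.counts.get(s, 0)
        left = histogram.counts.get(s - 1, 0)
        right = histogram.counts.get(s + 1, 0)
        if h >= left and h >= right and h >= 0.3 * modal_height:
            return True
    return False


def _snp_consensus(
    bases: list[str], consensus_frac: float
) -> str | None:
    if not bases:
        return None
    counter = Counter(bases)
    base, count = counter.most_common(1)[0]
    return base if count / len(bases) >= consensus_frac else None


def _partition_mode(counts: Counter[int]) -> int:
    """Modal size within one SNP partition (ties to smaller)."""
    return min(counts, key=lambda s: (-counts[s], s))


def phase_and_refine(
    observations: list[ReadObservation],
    modes: list[Mode],
    locus: RepeatLocus,
    sample_id: str = "sample",
    params: CallerParams = CallerParams(),
) -> SampleGenotype:
    """Resolve provisional modes into a diploid genotype.

    Two well-separated modes give a heterozygous call with reads assigned
    to the nearest mode.  A single mode is tested for a hidden second allele
    by partitioning its reads on the linked SNP base: two well-supported
    partitions with different modal sizes are reported as heterozygous;
    otherwise the sample is homozygous for the single mode.
    """
    if not modes:
        raise NoCallError("phase_and_refine requires at least one mode")
    usable = [
        o for o in observations
        if o.repeat_count is not None and o.repeat_count >= params.artefact_floor
    ]
    histogram = build_histogram(usable, params.artefact_floor)
    notes: list[str] = []
    site = locus.snp_sites[0] if locus.snp_sites else None

    def allele_from_reads(size: int, reads: list[ReadObservation]) -> AlleleCall:
        phase = None
        if site is not None:
            bases = [
                o.snp_calls.get(site.rsid)
                for o in reads
                if o.snp_calls.get(site.rsid) in (site.ref_base, site.alt_base)
            ]
            phase = _snp_consensus([b for b in bases if b], params.consensus_frac)
        sub_counts = Counter(o.repeat_count for o in reads)
        basin = tuple(sorted(sub_counts))
        mode = Mode(size=size, depth=len(reads), basin=basin)
        sub_hist = RepeatHistogram(dict(sub_counts), len(reads))
        return AlleleCall(
            size=size,
            depth=len(reads),
            classification=classify_allele(size),
            mosaic_flag=flag_mosaicism(sub_hist, mode),
            phase_base=phase,
        )

    if len(modes) == 2:
        groups: dict[int, list[ReadObservation]] = {m.size: [] for m in modes}
        for o in usable:
            nearest = min(modes, key=lambda m: (abs(o.repeat_count - m.size), m.size))
            groups[nearest.size].append(o)
        alleles = tuple(
            allele_from_reads(m.size, groups[m.size]) for m in sorted(modes, key=lambda m: m.size)
        )
        return SampleGenotype(sample_id, alleles, "heterozygous", tuple(notes))

    mode = modes[0]
    mode_reads = [o for o in usable if o.repeat_count in mode.basin]
    if site is not None:
        partitions: dict[str, list[ReadObservation]] = {}
        for o in mode_reads:
            base = o.snp_calls.get(site.rsid)
            if base in (site.ref_base, site.alt_base):
                partitions.setdefault(base, []).append(o)
        strong = {
            b: reads for b, reads in partitions.items() if len(reads) > params.depth_gate
        }
        if len(strong) == 2:
            sized = {
                b: _partition_mode(Counter(o.repeat_count for o in reads))
                for b, reads in strong.items()
            }
            if len(set(sized.values())) == 2:
                alleles = tuple(
                    allele_from_reads(sized[b], strong[b])
                    for b in sorted(strong, key=lambda b: sized[b])
                )
                notes.append("heterozygous alleles resolved by SNP phasing")
                return SampleGenotype(sample_id, alleles, "heterozygous", tuple(notes))
            notes.append("SNP-heterozygous but allele sizes indistinguishable")
            allele = allele_from_reads(mode.size, mode_reads)
            return SampleGenotype(
                sample_id, (allele, allele), "single-allele-low-confidence", tuple(notes)
            )
        if not partitions:
            notes.append("no SNP coverage; homozygosity assumed from unimodal histogram")
    allele = allele_from_reads(mode.size, mode_reads)
    return SampleGenotype(sample_id, (allele, allele), "homozygous", tuple(notes))


def call_genotype(
    observations: list[ReadObservation],
    locus: RepeatLocus,
    sample_id: str = "sample",
    params: CallerParams = CallerParams(),
) -> SampleGenotype:
    """Histogram, modes and phasing in one step."""
    histogram = build_histogram(observations, params.artefact_floor)
    modes = call_modes(histogram, params)
    return phase_and_refine(observations, modes, locus, sample_id, params)


# -- genotype table IO -----------------------------------------------------


def genotypes_to_frame(genotypes: list[SampleGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        a1 = g.alleles[0]
        a2 = g.alleles[1] if len(g.alleles) > 1 else g.alleles[0]
        rows.append(
            {
                "sample_id": g.sample_id,
                "allele1": a1.size,
                "allele2": a2.size,
                "depth1": a1.depth,
                "depth2": a2.depth,
                "class1": a1.classification,
                "class2": a2.classification,
                "zygosity": g.zygosity,
                "carrier": int(g.expansion_carrier),
                "mosaic1": int(a1.mosaic_flag),
                "mosaic2": int(a2.mosaic_flag),
                "phase1": a1.phase_base or ".",
                "phase2": a2.phase_base or ".",
            }
        )
    return pd.DataFrame(rows)


def frame_to_genotypes(frame: pd.DataFrame) -> list[SampleGenotype]:
    genotypes = []
    for _, row in frame.iterrows():
        alleles = tuple(
            AlleleCall(
                size=int(row[f"allele{i}"]),
                depth=int(row[f"depth{i}"]),
                classification=str(row[f"class{i}"]),
                mosaic_flag=bool(row[f"mosaic{i}"]),
                phase_base=None if row[f"phase{i}"] == "." else str(row[f"phase{i}"]),
            )
            for i in (1, 2)
        )
        genotypes.append(
            SampleGenotype(str(row["sample_id"]), alleles, str(row["zygosity"]))
        )
    return genotypes
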