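"""Repeat locus model: amplicon template, flanking anchors and linked SNP sites.

A :class:`RepeatLocus` describes one short-tandem-repeat amplicon: the left
and right flanking sequences that the PCR primers amplify, the repeat unit
between them, the genomic interval of the reference repeat tract (metadata
only — the pipeline works entirely in amplicon space), and any biallelic SNP
sites inside the flanks that can be used to phase reads to alleles.

Coordinate conventions
----------------------
Configs use 1-based inclusive genomic coordinates as printed in the
literature; every internal amplicon coordinate is 0-based half-open.
SNP offsets are counted from the first repeat base: a negative offset of
``-k`` addresses the k-th base upstream of the repeat tract (inside the left
flank), while a positive offset of ``+k`` addresses the k-th base downstream
of the tract (inside the right flank).  Offset 0 would be the first repeat
base and is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SnpSite",
    "RepeatLocus",
    "build_amplicon",
    "load_locus",
    "save_locus",
    "default_ctg18_locus",
    "LocusConfigError",
]

_ALPHABET = frozenset("ACGT")


class LocusConfigError(ValueError):
    """Raised when a locus configuration violates an invariant."""


def _check_sequence(name: str, seq: str) -> None:
    if not seq or set(seq) - _ALPHABET:
        raise LocusConfigError(
            f"{name} must be a non-empty string over {{A,C,G,T}}"
        )


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP inside the amplicon flanks, linked to the repeat.

    ``offset`` is signed, counted from the first repeat base (negative =
    upstream / proximal, inside the left flank).
    """

    rsid: str
    offset: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        _check_sequence("ref_base", self.ref_base)
        _check_sequence("alt_base", self.alt_base)
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise LocusConfigError("SNP alleles must be single bases")
        if self.ref_base == self.alt_base:
            raise LocusConfigError(
                f"SNP {self.rsid}: ref_base equals alt_base ({self.ref_base})"
            )
        if self.offset == 0:
            raise LocusConfigError(
                f"SNP {self.rsid}: offset 0 addresses the repeat tract itself"
            )


@dataclass(frozen=True)
class RepeatLocus:
    """Static description of a short-tandem-repeat amplicon."""

    name: str
    chrom: str
    repeat_start: int  # 1-based inclusive, genomic (metadata)
    repeat_end: int  # 1-based inclusive, genomic (metadata)
    left_flank: str
    right_flank: str
    unit: str = "CTG"
    anchor_len: int = 30
    snp_sites: tuple[SnpSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_sequence("unit", self.unit)
        _check_sequence("left_flank", self.left_flank)
        _check_sequence("right_flank", self.right_flank)
        span = self.repeat_end - self.repeat_start + 1
        if span <= 0 or span % len(self.unit) != 0:
            raise LocusConfigError(
                f"genomic interval {self.repeat_start}-{self.repeat_end} is not a "
                f"positive multiple of the {len(self.unit)}-base unit"
            )
        if self.anchor_len < 10:
            raise LocusConfigError("anchor_len must be at least 10 bases")
        if len(self.left_flank) < self.anchor_len or len(self.right_flank) < self.anchor_len:
            raise LocusConfigError(
                f"flanks must each be at least anchor_len={self.anchor_len} bases"
            )
        for site in self.snp_sites:
            try:
                self.snp_position(site)
            except IndexError:
                raise LocusConfigError(
                    f"SNP {site.rsid}: offset {site.offset} falls outside the flanks"
                ) from None

    # -- derived geometry -------------------------------------------------

    @property
    def reference_units(self) -> int:
        """Repeat units spanned by the genomic reference interval."""
        return (self.repeat_end - self.repeat_start + 1) // len(self.unit)

    @property
    def left_anchor(self) -> str:
        """Inner-most ``anchor_len`` bases of the left flank."""
        return self.left_flank[-self.anchor_len:]

    @property
    def right_anchor(self) -> str:
        """Inner-most ``anchor_len`` bases of the right flank."""
        return self.right_flank[: self.anchor_len]

    def snp_position(self, site: SnpSite) -> int:
        """0-based position of ``site`` within the amplicon's own flank.

        For a negative offset the position indexes into ``left_flank``;
        for a positive offset, into ``right_flank``.
        """
        if site.offset < 0:
            pos = len(self.left_flank) + site.offset
            if not 0 <= pos < len(self.left_flank):
                raise IndexError(site.rsid)
            return pos
        pos = site.offset - 1
        if not 0 <= pos < len(self.right_flank):
            raise IndexError(site.rsid)
        return pos

    def flank_base(self, site: SnpSite) -> str:
        """The base the shipped flank carries at the SNP position."""
        pos = self.snp_position(site)
        flank = self.left_flank if site.offset < 0 else self.right_flank
        return flank[pos]


def build_amplicon(
    locus: RepeatLocus,
    n_units: int,
    snp_bases: dict[str, str] | None = None,
) -> str:
    """Return the amplicon sequence ``left_flank + unit*n_units + right_flank``.

    ``snp_bases`` optionally substitutes a specific allele base at each named
    SNP site, producing a haplotype-specific amplicon.
    """
    if n_units < 0:
        raise ValueError(f"n_units must be non-negative, got {n_units}")
    left, right = locus.left_flank, locus.right_flank
    if snp_bases:
        sites = {s.rsid: s for s in locus.snp_sites}
        left_arr, right_arr = list(left), list(right)
        for rsid, base in snp_bases.items():
            if rsid not in sites:
                raise KeyError(f"unknown SNP site {rsid!r}")
            site = sites[rsid]
            pos = locus.snp_position(site)
            (left_arr if site.offset < 0 else right_arr)[pos] = base
        left, right = "".join(left_arr), "".join(right_arr)
    return left + locus.unit * n_units + right


# -- serialisation ---------------------------------------------------------


def load_locus(config_path: str | Path) -> RepeatLocus:
    """Load and validate a locus from a JSON config file."""
    path = Path(config_path)
    with open(path) as fh:
        raw = json.load(fh)
    return locus_from_dict(raw)


def locus_from_dict(raw: dict) -> RepeatLocus:
    required = ["name", "chrom", "repeat_start", "repeat_end", "left_flank", "right_flank"]
    for key in required:
        if key not in raw:
            raise LocusConfigError(f"locus config is missing required field {key!r}")
    snps = tuple(
        SnpSite(
            rsid=s["rsid"],
            offset=int(s["offset"]),
            ref_base=s["ref"].upper(),
            alt_base=s["alt"].upper(),
        )
        for s in raw.get("snps", [])
    )
    return RepeatLocus(
        name=str(raw["name"]),
        chrom=str(raw["chrom"]),
        repeat_start=int(raw["repeat_start"]),
        repeat_end=int(raw["repeat_end"]),
        left_flank=str(raw["left_flank"]).upper(),
        right_flank=str(raw["right_flank"]).upper(),
        unit=str(raw.get("unit", "CTG")).upper(),
        anchor_len=int(raw.get("anchor_len", 30)),
        snp_sites=snps,
    )


def locus_to_dict(locus: RepeatLocus) -> dict:
    d = asdict(locus)
    d["snps"] = [
        {"rsid": s["rsid"], "offset": s["offset"], "ref": s["ref_base"], "alt": s["alt_base"]}
        for s in d.pop("snp_sites")
    ]
    return d


def save_locus(locus: RepeatLocus, config_path: str | Path) -> None:
    with open(config_path, "w") as fh:
        json.dump(locus_to_dict(locus), fh, indent=2)
        fh.write("\n")


def amplicon_to_fasta(locus: RepeatLocus, n_units: int, path: str | Path) -> None:
    """Write ``build_amplicon(locus, n_units)`` as a single-record FASTA."""
    seq = build_amplicon(locus, n_units)
    with open(path, "w") as fh:
        fh.write(f">{locus.name}_{n_units}x{locus.unit}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# -- default CTG18.1 locus -------------------------------------------------

#: Total flank length of the default locus: with the 3-base CTG unit a
#: 25-repeat allele yields a 4,407-bp amplicon (4,332 + 75).
DEFAULT_FLANK_TOTAL = 4332

_RS599550 = SnpSite(rsid="rs599550", offset=-997, ref_base="G", alt_base="A")


def default_ctg18_locus(seed: int = 53253387) -> RepeatLocus:
    """The CTG18.1 (TCF4 intron 2) locus with synthetic flank sequence.

    The genomic interval (chr18:53,253,387-53,253,458 on hg19, 24 CTG units)
    and the rs599550 site (997 bp proximal to the repeat, G reference / A
    alternate) are real annotations.  The flank *sequences* are deterministic
    pseudo-random stand-ins of the correct total length (4,332 bp, so a
    25-repeat allele gives the expected 4,407-bp amplicon); real analyses
    should supply true flanks via a locus config.
    """
    rng = np.random.default_rng(seed)
    half = DEFAULT_FLANK_TOTAL // 2
    bases = np.array(list("ACGT"))
    left = rng.choice(bases, size=half)
    right = rng.choice(bases, size=DEFAULT_FLANK_TOTAL - half)
    # Neutral junction bases so the repeat tract cannot extend into a flank.
    left[-1] = "A"
    right[0] = "A"
    left[half + _RS599550.offset] = _RS599550.ref_base
    return RepeatLocus(
        name="CTG18.1",
        chrom="chr18",
        repeat_start=53_253_387,
        repeat_end=53_253_458,
        left_flank="".join(left),
        right_flank="".join(right),
        unit="CTG",
        anchor_len=30,
        snp_sites=(_RS599550,),
    )
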