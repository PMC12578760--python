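"""Per-allele haplotypes and repeat-SNP linkage tabulation.

Each called allele contributes one haplotype record: its repeat size,
expansion status (>= 50 units) and the SNP base carried in cis.  Case
haplotypes fall into three groups — expanded alleles (EXP-POS >= 50),
non-expanded partner alleles of expansion carriers (EXP-POS < 50), and
alleles of non-carrier samples (EXP-NEG < 50) — which are compared against
reference-population allele counts (e.g. gnomAD) with an exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calling import EXPANSION_THRESHOLD, SampleGenotype
from .stats import ContingencyTable, fisher_exact

__all__ = [
    "HaplotypeRecord",
    "LinkageTable",
    "GROUP_EXPANDED",
    "GROUP_CARRIER_PARTNER",
    "GROUP_NONCARRIER",
    "GROUP_POPULATION",
    "extract_haplotypes",
    "tabulate_linkage",
]

GROUP_EXPANDED = "EXP-POS(>=50)"
GROUP_CARRIER_PARTNER = "EXP-POS(<50)"
GROUP_NONCARRIER = "EXP-NEG(<50)"
GROUP_POPULATION = "population"

CASE_GROUPS = (GROUP_EXPANDED, GROUP_CARRIER_PARTNER, GROUP_NONCARRIER)


@dataclass(frozen=True)
class HaplotypeRecord:
    sample_id: str
    allele_size: int
    expansion_status: bool
    snp_base: str | None
    depth: int
    group: str

    def __post_init__(self) -> None:
        if self.expansion_status != (self.allele_size >= EXPANSION_THRESHOLD):
            raise ValueError("expansion_status inconsistent with allele_size")


def extract_haplotypes(genotypes: list[SampleGenotype]) -> list[HaplotypeRecord]:
    """One haplotype record per called allele, with its linkage group."""
    records: list[HaplotypeRecord] = []
    for g in genotypes:
        carrier = g.expansion_carrier
        for allele in g.alleles:
            expanded = allele.size >= EXPANSION_THRESHOLD
            if expanded:
                group = GROUP_EXPANDED
            elif carrier:
                group = GROUP_CARRIER_PARTNER
            else:
                group = GROUP_NONCARRIER
            records.append(
                HaplotypeRecord(
                    sample_id=g.sample_id,
                    allele_size=allele.size,
                    expansion_status=expanded,
                    snp_base=allele.phase_base,
                    depth=allele.depth,
                    group=group,
                )
            )
    return records


@dataclass
class LinkageTable:
    """Per-group SNP base counts, frequencies and exact-test p-values.

    ``groups`` maps group name -> {base: count}; ``excluded`` counts alleles
    whose SNP base could not be resolved.  The reference population's counts
    are stored under :data:`GROUP_POPULATION`.
    """

    rsid: str
    bases: tuple[str, str]  # (ref, alt) order used for tabulation
    groups: dict[str, dict[str, int]]
    excluded: dict[str, int]

    def frequency(self, group: str, base: str) -> float | None:
        counts = self.groups.get(group, {})
        total = sum(counts.values())
        if total == 0:
            return None
        return counts.get(base, 0) / total

    def p_value_vs_population(self, group: str) -> float | None:
        """Exact two-sided p for this group's base counts vs the population."""
        pop = self.groups.get(GROUP_POPULATION)
        counts = self.groups.get(group)
        if not pop or not counts:
            return None
        b1, b2 = self.bases
        table = ContingencyTable(
            counts.get(b1, 0), counts.get(b2, 0), pop.get(b1, 0), pop.get(b2, 0)
        )
        return fisher_exact(table)

    def to_frame(self) -> pd.DataFrame:
        b1, b2 = self.bases
        rows = []
        for group in (GROUP_POPULATION,) + CASE_GROUPS:
            counts = self.groups.get(group, {})
            total = sum(counts.values())
            rows.append(
                {
                    "group": group,
                    "n_alleles": total,
                    f"count_{b1}": counts.get(b1, 0),
                    f"freq_{b1}": round(counts.get(b1, 0) / total, 4) if total else float("nan"),
                    f"count_{b2}": counts.get(b2, 0),
                    f"freq_{b2}": round(counts.get(b2, 0) / total, 4) if total else float("nan"),
                    "excluded": self.excluded.get(group, 0),
                    "p_vs_population": (
                        float("nan")
                        if group == GROUP_POPULATION
                        else (self.p_value_vs_population(group) or float("nan"))
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tabulate_linkage(
    haplotypes: list[HaplotypeRecord],
    population_counts: dict[str, int],
    rsid: str = "rs599550",
    bases: tuple[str, str] | None = None,
) -> LinkageTable:
    """Cross-tabulate SNP bases by linkage group against a population.

    ``population_counts`` maps base -> allele count in the reference
    population (e.g. the printed gnomAD European non-Finnish counts).
    Haplotypes with an unresolved SNP base are excluded and tallied.
    """
    if bases is None:
        named = sorted(population_counts, key=population_counts.get, reverse=True)
        if len(named) < 2:
            raise ValueError("population_counts must name at least two bases")
        bases = (named[0], named[1])
    groups: dict[str, dict[str, int]] = {g: {} for g in CASE_GROUPS}
    excluded: dict[str, int] = {}
    for record in haplotypes:
        if record.snp_base is None or record.snp_base not in bases:
            excluded[record.group] = excluded.get(record.group, 0) + 1
            continue
        counts = groups.setdefault(record.group, {})
        counts[record.snp_base] = counts.get(record.snp_base, 0) + 1
    groups[GROUP_POPULATION] = {b: int(population_counts.get(b, 0)) for b in bases}
    return LinkageTable(rsid=rsid, bases=bases, groups=groups, excluded=excluded)


def linkage_from_counts(
    group_counts: dict[str, dict[str, int]],
    population_counts: dict[str, int],
    rsid: str = "rs599550",
    bases: tuple[str, str] | None = None,
) -> LinkageTable:
    """Build a LinkageTable directly from published per-group base counts."""
    if bases is None:
        named = sorted(population_counts, key=population_counts.get, reverse=True)
        bases = (named[0], named[1])
    groups = {g: dict(c) for g, c in group_counts.items()}
    groups[GROUP_POPULATION] = {b: int(population_counts.get(b, 0)) for b in bases}
    return LinkageTable(rsid=rsid, bases=bases, groups=groups, excluded={})
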