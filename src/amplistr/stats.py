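"""Case-control statistics on 2x2 contingency tables and cohort summaries.

The exact test is implemented from first principles: under fixed margins the
first cell follows a hypergeometric distribution, and the two-sided p-value
sums the probabilities of all tables as or less probable than the one
observed.  Probabilities are computed through log-gamma, so margins up to
about 10^6 (population-scale allele counts) remain numerically stable.

Two association ratios are reported side by side because published 2x2
summaries do not always use the cross-product odds ratio:

* ``carrier_risk_ratio`` — the ratio of carrier *proportions*,
  (a/(a+b)) / (c/(c+d));
* ``odds_ratio`` — the conventional cross-product (a*d)/(b*c), optionally
  Haldane-Anscombe corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .calling import INTERMEDIATE_BAND, SampleGenotype

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "carrier_risk_ratio",
    "odds_ratio",
    "CohortReport",
    "summarize_cohort",
]

#: Relative tolerance guard when comparing table probabilities to the
#: observed one: protects the "probability <= observed" rule from
#: floating-point noise on large margins.
_P_TOLERANCE = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows are groups, columns outcome present/absent.

    ::

            outcome+  outcome-
      row1      a         b
      row2      c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError(f"table cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(first cell = k) under fixed margins (r1, r2 rows; c1 first column)."""
    n = r1 + r2

    def logc(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logc(r1, k) + logc(r2, c1 - k) - logc(n, c1)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact p-value for independence in a 2x2 table.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (with a
    small relative tolerance guard).  A degenerate table (an all-zero row or
    column) carries no information and returns 1.0 with a warning.
    """
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        warnings.warn("degenerate margin in 2x2 table; p-value is 1.0", stacklevel=2)
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_pmf = _log_hypergeom_pmf(k, r1, r2, c1)
    log_obs = _log_hypergeom_pmf(np.array([table.a]), r1, r2, c1)[0]
    include = log_pmf <= log_obs + math.log1p(_P_TOLERANCE)
    p = float(np.exp(log_pmf[include]).sum())
    return min(p, 1.0)


def carrier_risk_ratio(table: ContingencyTable) -> float | None:
    """Ratio of row-wise outcome proportions: (a/(a+b)) / (c/(c+d)).

    Undefined (None) when the second row has no positive outcomes (c = 0)
    or either row is empty.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    if table.c == 0 or r1 == 0 or r2 == 0:
        return None
    return (table.a / r1) / (table.c / r2)


def odds_ratio(table: ContingencyTable, haldane_correction: bool = False) -> float | None:
    """Cross-product odds ratio (a*d)/(b*c).

    With ``haldane_correction`` 0.5 is added to every cell whenever any cell
    is zero; without it a zero in b or c makes the ratio undefined (None).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane_correction and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return None
    return (a * d) / (b * c)


@dataclass
class CohortReport:
    """Carrier statistics for a case arm and a control arm."""

    n_cases: int
    n_controls: int
    case_carriers: int
    control_carriers: int
    case_monoallelic: int
    case_biallelic: int
    control_monoallelic: int
    control_biallelic: int
    case_allele_sizes: list[int] = field(default_factory=list)
    control_allele_sizes: list[int] = field(default_factory=list)
    intermediate_alleles: list[tuple[str, int]] = field(default_factory=list)

    @property
    def case_carrier_pct(self) -> float | None:
        return 100.0 * self.case_carriers / self.n_cases if self.n_cases else None

    @property
    def control_carrier_pct(self) -> float | None:
        return 100.0 * self.control_carriers / self.n_controls if self.n_controls else None

    @property
    def carrier_table(self) -> ContingencyTable | None:
        if self.n_cases == 0 or self.n_controls == 0:
            return None
        return ContingencyTable(
            self.case_carriers,
            self.n_cases - self.case_carriers,
            self.control_carriers,
            self.n_controls - self.control_carriers,
        )

    @property
    def p_value(self) -> float | None:
        table = self.carrier_table
        return fisher_exact(table) if table is not None else None

    @property
    def carrier_ratio(self) -> float | None:
        table = self.carrier_table
        return carrier_risk_ratio(table) if table is not None else None

    @property
    def cross_product_odds_ratio(self) -> float | None:
        table = self.carrier_table
        return odds_ratio(table) if table is not None else None

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "case_carriers": self.case_carriers,
            "control_carriers": self.control_carriers,
            "case_carrier_pct": self.case_carrier_pct,
            "control_carrier_pct": self.control_carrier_pct,
            "case_monoallelic": self.case_monoallelic,
            "case_biallelic": self.case_biallelic,
            "control_monoallelic": self.control_monoallelic,
            "control_biallelic": self.control_biallelic,
            "fisher_p": self.p_value,
            "carrier_proportion_ratio": self.carrier_ratio,
            "cross_product_odds_ratio": self.cross_product_odds_ratio,
            "n_intermediate_alleles": len(self.intermediate_alleles),
        }


def _arm_stats(genotypes: list[SampleGenotype]) -> tuple[int, int, int, list[int]]:
    carriers = mono = bi = 0
    sizes: list[int] = []
    for g in genotypes:
        sizes.extend(a.size for a in g.alleles)
        if g.expansion_carrier:
            carriers += 1
            if g.biallelic_expansion:
                bi += 1
            else:
                mono += 1
    return carriers, mono, bi, sizes


def summarize_cohort(
    genotypes_cases: list[SampleGenotype],
    genotypes_controls: list[SampleGenotype],
) -> CohortReport:
    """Carrier counts, percentages, exact test and association ratios.

    Also flags every allele in the advisory intermediate band
    (35-49 units); intermediate alleles never affect carrier statistics,
    which use the >= 50 rule exclusively.
    """
    case_carriers, case_mono, case_bi, case_sizes = _arm_stats(genotypes_cases)
    ctrl_carriers, ctrl_mono, ctrl_bi, ctrl_sizes = _arm_stats(genotypes_controls)
    intermediates = [
        (g.sample_id, a.size)
        for g in list(genotypes_cases) + list(genotypes_controls)
        for a in g.alleles
        if INTERMEDIATE_BAND[0] <= a.size <= INTERMEDIATE_BAND[1]
    ]
    return CohortReport(
        n_cases=len(genotypes_cases),
        n_controls=len(genotypes_controls),
        case_carriers=case_carriers,
        control_carriers=ctrl_carriers,
        case_monoallelic=case_mono,
        case_biallelic=case_bi,
        control_monoallelic=ctrl_mono,
        control_biallelic=ctrl_bi,
        case_allele_sizes=sorted(case_sizes),
        control_allele_sizes=sorted(ctrl_sizes),
        intermediate_alleles=intermediates,
    )
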