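"""Carrier-frequency and odds-ratio statistics for case/control comparisons.

Carriers are assumed heterozygous, so the minor allele frequency is
carriers / (2·individuals). Odds ratios use a 2×2 table of carrier vs
non-carrier individuals per group with a Woolf (log-normal) 95% confidence
interval, exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); this construction
reproduces the published worked example (5/6,252 cases vs 1/3,877 controls →
OR 3.10, CI 0.36–26.56) to the printed precision. When a cell is zero the
Haldane–Anscombe correction (+0.5 to every cell) is applied and flagged.

For comparisons against a reference population reported only as an allele
frequency, :func:`frequency_vs_reference` builds both sides of the table on
allele counts instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .exceptions import UndefinedEffectError

Z95 = 1.96


@dataclass(frozen=True)
class CarrierCounts:
    cases_carriers: int
    cases_n: int  # diploid individuals
    controls_carriers: int
    controls_n: int

    def __post_init__(self):
        for name in ("cases_carriers", "cases_n", "controls_carriers", "controls_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cases_carriers > self.cases_n:
            raise ValueError("cases_carriers exceeds cases_n")
        if self.controls_carriers > self.controls_n:
            raise ValueError("controls_carriers exceeds controls_n")


@dataclass(frozen=True)
class AssociationResult:
    maf_cases: float
    maf_controls: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    correction_applied: bool = False

    def __post_init__(self):
        if not self.ci95_low <= self.odds_ratio <= self.ci95_high:
            raise ValueError("confidence interval does not contain the point estimate")


def allele_frequency(carriers: int, n_individuals: int) -> float:
    """Minor allele frequency under the heterozygous-carrier assumption."""
    if n_individuals == 0:
        raise ZeroDivisionError("allele frequency undefined for 0 individuals")
    if carriers > n_individuals:
        raise ValueError("more carriers than individuals")
    return carriers / (2 * n_individuals)


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percent string, rounding half away from zero
    (0.0025979 → "0.26%")."""
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{pct}%"


def _woolf(a: float, b: float, c: float, d: float) -> tuple[float, float, float, bool]:
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - Z95 * se)
    hi = math.exp(math.log(orr) + Z95 * se)
    return orr, lo, hi, corrected


def odds_ratio(counts: CarrierCounts) -> AssociationResult:
    """Case/control odds ratio on carrier counts with Woolf 95% CI."""
    if counts.cases_carriers == 0 and counts.controls_carriers == 0:
        raise UndefinedEffectError("no carriers in either group")
    a = counts.cases_carriers
    b = counts.cases_n - counts.cases_carriers
    c = counts.controls_carriers
    d = counts.controls_n - counts.controls_carriers
    orr, lo, hi, corrected = _woolf(a, b, c, d)
    return AssociationResult(
        maf_cases=allele_frequency(counts.cases_carriers, counts.cases_n),
        maf_controls=allele_frequency(counts.controls_carriers, counts.controls_n),
        odds_ratio=orr,
        ci95_low=lo,
        ci95_high=hi,
        correction_applied=corrected,
    )


def frequency_vs_reference(
    carriers: int,
    n_individuals: int,
    reference_maf: float,
    reference_alleles: int,
) -> AssociationResult:
    """Compare a carrier count against a reference population for which only
    an allele frequency (and a total allele count) is known; both sides of
    the 2×2 are allele counts."""
    if reference_alleles <= 0:
        raise ValueError("reference_alleles must be positive")
    if not 0 <= reference_maf < 1:
        raise ValueError("reference_maf must be in [0, 1)")
    a = carriers
    b = 2 * n_individuals - carriers
    c = round(reference_maf * reference_alleles)
    d = reference_alleles - c
    if a == 0 and c == 0:
        raise UndefinedEffectError("no carrier alleles in either group")
    orr, lo, hi, corrected = _woolf(a, b, c, d)
    return AssociationResult(
        maf_cases=allele_frequency(carriers, n_individuals),
        maf_controls=reference_maf,
        odds_ratio=orr,
        ci95_low=lo,
        ci95_high=hi,
        correction_applied=corrected,
    )


def format_or_ci(result: AssociationResult) -> str:
    """Render "OR (low–high)" to two decimals, e.g. "3.10 (0.36–26.56)"."""
    return (
        f"{result.odds_ratio:.2f} "
        f"({result.ci95_low:.2f}–{result.ci95_high:.2f})"
    )
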