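"""Census-based demographic calculators feeding the age estimators.

Covers the small amount of demographic arithmetic the dating analysis needs:
a per-generation exponential growth rate from a pair of censuses
(``N = N0 * exp(g p)``), Hardy-Weinberg allele frequencies from homozygote
counts, disease prevalence as a ``1:K`` ratio, the sampled-chromosome
proportion required by Bayesian LD dating software, and generation/year
conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "CensusPair",
    "GrowthRate",
    "Prevalence",
    "SampledProportionMethod",
    "growth_rate",
    "hwe_allele_freq",
    "prevalence",
    "sampled_proportion",
    "generations_to_years",
]

DEFAULT_GENERATION_TIME = 30.0


@dataclass(frozen=True)
class CensusPair:
    """Two census counts of the same population at different calendar years."""

    present: int
    reference: int
    present_year: int = 2011
    reference_year: int = 1591
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        if self.present <= 0 or self.reference <= 0:
            raise ValueError("census counts must be positive")
        if self.present_year <= self.reference_year:
            raise ValueError("present_year must be after reference_year")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")


@dataclass(frozen=True)
class GrowthRate:
    """Per-generation exponential growth rate and the generation count used."""

    rate: float
    generations: int


def growth_rate(census: CensusPair) -> GrowthRate:
    """Exponential per-generation growth rate from a census pair.

    ``g`` is the (nearest-integer) number of generations between the
    censuses; ``p = ln(N / N0) / g`` solves ``N = N0 * exp(g p)``.
    """
    g = round((census.present_year - census.reference_year) / census.generation_time)
    if g <= 0:
        raise ValueError("census years are less than one generation apart")
    p = math.log(census.present / census.reference) / g
    return GrowthRate(rate=p, generations=int(g))


def hwe_allele_freq(n_homozygotes: int, population: int) -> float:
    """Allele frequency ``q = sqrt(homozygotes / population)`` under
    Hardy-Weinberg equilibrium (recessive disease, all cases ascertained)."""
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= n_homozygotes <= population:
        raise ValueError("homozygote count must lie in [0, population]")
    return math.sqrt(n_homozygotes / population)


@dataclass(frozen=True)
class Prevalence:
    """Disease prevalence as a 1:K ratio."""

    k: int
    k_exact: float
    round_to: int

    def __str__(self) -> str:
        return f"1:{self.k:,}"


def prevalence(n_cases: int, population: int, round_to: int = 1000) -> Prevalence:
    """Prevalence ``1:K`` with ``K = population / cases`` rounded to
    ``round_to`` (default nearest 1,000)."""
    if n_cases < 1:
        raise ValueError("prevalence is undefined with zero cases")
    if population <= 0:
        raise ValueError("population must be positive")
    k_exact = population / n_cases
    k = int(round(k_exact / round_to) * round_to) if round_to > 1 else int(round(k_exact))
    if k == 0:  # ratio finer than the requested rounding (e.g. 1:1)
        k = max(int(round(k_exact)), 1)
    return Prevalence(k=k, k_exact=k_exact, round_to=round_to)


class SampledProportionMethod(str, Enum):
    """How the sampled fraction of mutation-carrying chromosomes is computed.

    The natural reading divides the sampled disease chromosomes by the
    expected number of mutant chromosomes in the population,
    ``q * 2 * population`` (``CHROMOSOMES``); ``INDIVIDUALS`` divides by the
    expected carrier-individual count ``q * population`` instead.  The method
    used is recorded alongside the result because published analyses do not
    always state theirs.
    """

    CHROMOSOMES = "chromosomes"
    INDIVIDUALS = "individuals"


def sampled_proportion(
    n_sampled_chromosomes: int,
    q: float,
    population: int,
    method: SampledProportionMethod = SampledProportionMethod.CHROMOSOMES,
) -> float:
    """Fraction of the population's mutation-carrying chromosomes sampled."""
    if q <= 0:
        raise ValueError("allele frequency q must be > 0")
    if population <= 0:
        raise ValueError("population must be positive")
    if n_sampled_chromosomes < 0:
        raise ValueError("sampled chromosome count must be >= 0")
    method = SampledProportionMethod(method)
    denom = q * population * (2.0 if method is SampledProportionMethod.CHROMOSOMES else 1.0)
    return min(n_sampled_chromosomes / denom, 1.0)


def generations_to_years(g: float, generation_time: float = DEFAULT_GENERATION_TIME) -> float:
    """Convert generations to calendar years."""
    if g < 0:
        raise ValueError("generation count must be >= 0")
    return g * generation_time
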