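"""Unit conversions between mutation-scaled and natural demographic units.

Coalescent-based inference reports divergence times as tau = T * mu
(expected substitutions per site) and population sizes as theta = 4*Ne*mu.
Converting those to years and diploid individuals requires an assumed
per-generation mutation rate and a generation time; for canids the
conventional values are mu = 1e-8 per site per generation on CpG-filtered
sites and a three-year generation.  Because CpG dinucleotides are removed
before genotyping but contribute roughly 30% of all mutations, the filtered
rate understates the genome-wide rate by a factor 1/(1 - cpg_fraction);
both scales are handled here, along with the propagation of mutation-rate
uncertainty into calendar-time intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "CalibrationParams",
    "calibrate_time",
    "years_to_tau",
    "calibrate_ne",
    "ne_to_theta",
    "genomewide_rate",
    "filtered_rate",
    "rate_sensitivity",
    "fold_reduction",
    "migration_convert",
    "round_sig",
]

#: Default per-generation mutation rate on filtered (non-CpG) sites.
DEFAULT_MU = 1e-8
#: Default generation time in years.
DEFAULT_GEN_TIME = 3.0
#: Default fraction of mutations contributed by CpG sites.
DEFAULT_CPG_FRACTION = 0.30


@dataclass(frozen=True)
class CalibrationParams:
    """Assumed mutation rate and generation time used for calibration.

    Parameters
    ----------
    mu_filtered : float
        Mutations per site per generation on filtered (non-CpG) sites.
    gen_time : float
        Years per generation.
    cpg_fraction : float
        Fraction of all mutations contributed by CpG sites, in [0, 1).
    """

    mu_filtered: float = DEFAULT_MU
    gen_time: float = DEFAULT_GEN_TIME
    cpg_fraction: float = DEFAULT_CPG_FRACTION

    def __post_init__(self):
        if self.mu_filtered <= 0:
            raise InvalidParameterError("mu_filtered must be > 0")
        if self.gen_time <= 0:
            raise InvalidParameterError("gen_time must be > 0")
        if not (0 <= self.cpg_fraction < 1):
            raise InvalidParameterError("cpg_fraction must be in [0, 1)")


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def calibrate_time(tau: float, params: CalibrationParams) -> float:
    """Convert a mutation-scaled divergence tau = T*mu to years.

    years = tau / mu_filtered * gen_time.  Inverse: :func:`years_to_tau`.
    """
    if tau < 0:
        raise InvalidParameterError("tau must be >= 0")
    return tau / params.mu_filtered * params.gen_time


def years_to_tau(years: float, params: CalibrationParams) -> float:
    """Inverse of :func:`calibrate_time`."""
    if years < 0:
        raise InvalidParameterError("years must be >= 0")
    return years / params.gen_time * params.mu_filtered


def calibrate_ne(theta: float, mu: float) -> float:
    """Convert mutation-scaled diversity theta = 4*Ne*mu to diploid Ne."""
    if mu <= 0:
        raise InvalidParameterError("mu must be > 0")
    if theta < 0:
        raise InvalidParameterError("theta must be >= 0")
    return theta / (4.0 * mu)


def ne_to_theta(ne: float, mu: float) -> float:
    """Inverse of :func:`calibrate_ne`."""
    if mu <= 0:
        raise InvalidParameterError("mu must be > 0")
    if ne < 0:
        raise InvalidParameterError("ne must be >= 0")
    return 4.0 * ne * mu


def genomewide_rate(mu_filtered: float, cpg_fraction: float) -> float:
    """Genome-wide mutation rate implied by a filtered-site rate.

    CpG sites are removed before genotyping but contribute
    ``cpg_fraction`` of all mutations, so
    mu_genomewide = mu_filtered / (1 - cpg_fraction).
    """
    if mu_filtered <= 0:
        raise InvalidParameterError("mu_filtered must be > 0")
    if not (0 <= cpg_fraction < 1):
        raise InvalidParameterError("cpg_fraction must be in [0, 1)")
    return mu_filtered / (1.0 - cpg_fraction)


def filtered_rate(mu_genomewide: float, cpg_fraction: float) -> float:
    """Inverse of :func:`genomewide_rate`."""
    if mu_genomewide <= 0:
        raise InvalidParameterError("mu_genomewide must be > 0")
    if not (0 <= cpg_fraction < 1):
        raise InvalidParameterError("cpg_fraction must be in [0, 1)")
    return mu_genomewide * (1.0 - cpg_fraction)


def rate_sensitivity(
    tau_interval: tuple[float, float],
    mu_gw_interval: tuple[float, float],
    cpg_fraction: float = DEFAULT_CPG_FRACTION,
    gen_time: float = DEFAULT_GEN_TIME,
    round_ky: bool = True,
) -> tuple[float, float]:
    """Propagate mutation-rate uncertainty into a divergence-time interval.

    Each bound of ``mu_gw_interval`` (genome-wide, per-generation rates)
    is first rescaled to the filtered-site scale via
    :func:`filtered_rate`, because tau was estimated on filtered sites.
    The calendar interval is then
    (tau_lo / mu_max * g, tau_hi / mu_min * g).

    Returns the interval in kiloyears, rounded to the nearest ky when
    ``round_ky`` (the reporting convention); unrounded years / 1000
    otherwise.
    """
    tau_lo, tau_hi = tau_interval
    mu_lo, mu_hi = mu_gw_interval
    if tau_lo > tau_hi or mu_lo > mu_hi:
        raise InvalidParameterError("interval bounds are crossed")
    if tau_lo < 0 or mu_lo <= 0:
        raise InvalidParameterError("intervals must be positive")
    mu_filt_lo = filtered_rate(mu_lo, cpg_fraction)
    mu_filt_hi = filtered_rate(mu_hi, cpg_fraction)
    lo_ky = tau_lo / mu_filt_hi * gen_time / 1000.0
    hi_ky = tau_hi / mu_filt_lo * gen_time / 1000.0
    if round_ky:
        return (round(lo_ky), round(hi_ky))
    return (lo_ky, hi_ky)


def fold_reduction(ne_from: float, ne_to: float, one_decimal: bool = False) -> float:
    """Fold change ne_from / ne_to between two population sizes."""
    if ne_from <= 0 or ne_to <= 0:
        raise InvalidParameterError("population sizes must be > 0")
    fold = ne_from / ne_to
    return round(fold, 1) if one_decimal else fold


def migration_convert(
    m_tot: float, band_duration: float, ne_target: float
) -> tuple[float, float, float]:
    """Decompose a total migration rate into per-generation quantities.

    ``m_tot`` is the expected number of migration events per lineage over
    the interval during which the two populations coexist (m * duration).
    Returns ``(m, migrants, probability)`` where ``m = m_tot/duration`` is
    the per-generation, per-lineage rate, ``migrants = 4*Ne*m`` the
    population-scaled migrant rate, and ``probability = 1 - exp(-m_tot)``
    the chance that a lineage migrates at least once through the band.
    """
    if band_duration <= 0:
        raise InvalidParameterError("band_duration must be > 0")
    if m_tot < 0 or ne_target < 0:
        raise InvalidParameterError("m_tot and ne_target must be >= 0")
    m = m_tot / band_duration
    migrants = 4.0 * ne_target * m
    probability = 1.0 - math.exp(-m_tot)
    return (m, migrants, probability)
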