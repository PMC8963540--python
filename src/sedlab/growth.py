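"""DNA-content and size analytics for the coenocytic growth cycle.

Covers the geometric-mean nuclear content of ploidy distributions, nuclear
doubling times by regression of log2 content against time, nuclei-per-volume
ratios, and the evolution-experiment generation ledger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import linregress

from .errors import DomainError, EstimationError, InputError

__all__ = [
    "NucleiDistribution",
    "DoublingEstimate",
    "GenerationLedger",
    "log2_geometric_mean",
    "nuclear_doubling_time",
    "nuclear_volume_ratio",
    "generations_accounting",
]

#: r-squared below which a doubling estimate is flagged as low confidence.
LOW_CONFIDENCE_R2 = 0.8

_FRACTION_TOL = 1e-9


@dataclass
class NucleiDistribution:
    """Fractions of coenocytes per nuclei-count bin at one time point."""

    time: float  # hours
    bins: list[tuple[int, float]]  # (nuclei per coenocyte, fraction)
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if not self.bins:
            raise InputError("distribution has no bins")
        for ploidy, frac in self.bins:
            if ploidy < 1 or int(ploidy) != ploidy:
                raise InputError(f"ploidy values must be positive integers, got {ploidy}")
            if frac < 0:
                raise InputError("fractions must be >= 0")
        total = sum(f for _, f in self.bins)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise InputError(f"fractions must sum to 1 (got {total})")

    @classmethod
    def from_counts(cls, time: float, counts: dict[int, int]) -> "NucleiDistribution":
        """Build a distribution from raw per-bin cell counts."""
        n = sum(counts.values())
        if n <= 0:
            raise InputError("counts must be positive")
        bins = [(ploidy, c / n) for ploidy, c in sorted(counts.items()) if c > 0]
        return cls(time=time, bins=bins, n_cells=n)


def log2_geometric_mean(dist: NucleiDistribution) -> float:
    """log2 of the geometric-mean nuclei count: ``sum_i f_i * log2(x_i)``."""
    return float(sum(frac * np.log2(ploidy) for ploidy, frac in dist.bins))


@dataclass(frozen=True)
class DoublingEstimate:
    """Nuclear doubling time from a regression of log2 content against time."""

    doubling_time: float  # hours
    slope: float  # log2 units per hour
    fit_window: tuple[float, float]
    r_squared: float
    low_confidence: bool  # r^2 below LOW_CONFIDENCE_R2 (e.g. asynchronous growth)
    n_points: int


def nuclear_doubling_time(
    series: list[NucleiDistribution],
    window: tuple[float, float] = (0.0, 24.0),
) -> DoublingEstimate:
    """Least-squares slope of log2 geometric-mean content versus time inside ``window``.

    The doubling time is the reciprocal of the slope.  A non-positive slope
    (no net nuclear growth) raises; poorly synchronised series come back with
    a ``low_confidence`` flag rather than failing.
    """
    inside = [d for d in series if window[0] <= d.time <= window[1]]
    if len(inside) < 2:
        raise InputError(f"need >= 2 time points inside window {window}")
    t = np.array([d.time for d in inside], dtype=float)
    y = np.array([log2_geometric_mean(d) for d in inside], dtype=float)
    res = linregress(t, y)
    slope = float(res.slope)
    if slope <= 0:
        raise EstimationError("no net nuclear growth: regression slope is non-positive")
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return DoublingEstimate(
        doubling_time=1.0 / slope,
        slope=slope,
        fit_window=window,
        r_squared=r2,
        low_confidence=r2 < LOW_CONFIDENCE_R2,
        n_points=len(inside),
    )


def nuclear_volume_ratio(nuclei_count: int, volume: float) -> float:
    """Nuclei per unit coenocyte volume (unit: reciprocal of the volume unit)."""
    if nuclei_count < 1:
        raise DomainError("nuclei_count must be >= 1")
    if volume <= 0:
        raise DomainError("volume must be > 0")
    return nuclei_count / volume


@dataclass(frozen=True)
class GenerationLedger:
    """Exact generation accounting for the evolution experiment."""

    transfers: int
    subpassages_per_cycle: int
    cycles: Fraction
    doublings_per_cycle: Fraction
    total_generations: Fraction
    population_size: int | None = None

    @property
    def total_generations_float(self) -> float:
        return float(self.total_generations)


def generations_accounting(
    transfers: int,
    subpassages_per_cycle: int,
    doublings_per_cycle,
    population_size: int | None = None,
) -> GenerationLedger:
    """cycles = transfers / subpassages_per_cycle; generations = cycles * doublings.

    Exact rational arithmetic throughout; a transfer count not divisible by the
    subpassages per cycle yields fractional cycles with a warning.
    """
    if transfers <= 0 or subpassages_per_cycle <= 0:
        raise DomainError("transfers and subpassages_per_cycle must be positive")
    doublings = Fraction(doublings_per_cycle)
    if doublings <= 0:
        raise DomainError("doublings_per_cycle must be positive")
    cycles = Fraction(transfers, subpassages_per_cycle)
    if cycles.denominator != 1:
        warnings.warn(
            f"{transfers} transfers is not a whole number of {subpassages_per_cycle}-subpassage "
            f"cycles; reporting fractional cycles {cycles}",
            stacklevel=2,
        )
    return GenerationLedger(
        transfers=transfers,
        subpassages_per_cycle=subpassages_per_cycle,
        cycles=cycles,
        doublings_per_cycle=doublings,
        total_generations=cycles * doublings,
        population_size=population_size,
    )
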