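"""Selection-coefficient estimation from clumpy/non-clumpy competition counts.

The frequency of the clumpy phenotype over time is put on the log2-odds scale,
rescaled to its initial measurement, and its slope against time (in days) is
the log2 selection coefficient per day.  Uncertainty comes from binomially
resampling each count at its observed proportion and total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import DomainError, EstimationError, InputError

__all__ = [
    "CompetitionTimeSeries",
    "SelectionEstimate",
    "proportion_ci",
    "logit2",
    "logit2_trajectory",
    "selection_coefficient",
    "proportion_summary",
]

_Z95 = float(norm.ppf(0.975))


@dataclass
class CompetitionTimeSeries:
    """Clumpy counts versus total counts over days for one genotype pair and regime.

    ``trajectory_ids`` labels independent replicates (batch/rep); points sharing
    a label are rescaled to that trajectory's own t=0 measurement.
    """

    label: str
    regime: str
    times_days: np.ndarray
    clumpy_counts: np.ndarray
    total_counts: np.ndarray
    trajectory_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.clumpy_counts = np.asarray(self.clumpy_counts, dtype=int)
        self.total_counts = np.asarray(self.total_counts, dtype=int)
        n = self.times_days.size
        if not (self.clumpy_counts.size == n and self.total_counts.size == n):
            raise InputError("times, clumpy and total counts must have equal length")
        if np.any(self.total_counts <= 0):
            raise InputError("total counts must be > 0")
        if np.any(self.clumpy_counts < 0) or np.any(self.clumpy_counts > self.total_counts):
            raise InputError("clumpy counts must satisfy 0 <= clumpy <= total")
        if np.any(self.times_days < 0):
            raise InputError("times must be non-negative")
        if self.trajectory_ids is None:
            self.trajectory_ids = np.zeros(n, dtype=int)
        else:
            self.trajectory_ids = np.asarray(self.trajectory_ids)
            if self.trajectory_ids.size != n:
                raise InputError("trajectory_ids must match the number of observations")

    @property
    def proportions(self) -> np.ndarray:
        return self.clumpy_counts / self.total_counts

    def relabeled(self) -> "CompetitionTimeSeries":
        """Swap the clumpy and non-clumpy categories."""
        return CompetitionTimeSeries(
            label=self.label,
            regime=self.regime,
            times_days=self.times_days,
            clumpy_counts=self.total_counts - self.clumpy_counts,
            total_counts=self.total_counts,
            trajectory_ids=self.trajectory_ids,
        )


@dataclass(frozen=True)
class SelectionEstimate:
    """Log2 selection coefficient per day with resampling-based uncertainty."""

    coefficient: float
    standard_error: float
    ci95: tuple[float, float]
    p_value: float  # approximate two-sided normal tail; construction not from the source
    n_resamples: int
    seed: int | None
    slopes: np.ndarray = field(repr=False, default=None)


def proportion_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float, float]:
    """Logit-interval binomial CI: normal interval on log-odds, back-transformed.

    SE on the log-odds scale is ``sqrt(1/k + 1/(n-k))``.  Boundary counts get a
    half-count (Haldane-Anscombe) correction for the interval; the bound at the
    boundary side is pinned to 0 or 1.
    """
    if trials <= 0:
        raise InputError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise InputError("successes must satisfy 0 <= k <= n")
    point = successes / trials
    z = float(norm.ppf(0.5 + level / 2.0))
    k, n = float(successes), float(trials)
    at_lower, at_upper = successes == 0, successes == trials
    if at_lower or at_upper:
        k, n = k + 0.5, n + 1.0
    logit = np.log(k / (n - k))
    se = np.sqrt(1.0 / k + 1.0 / (n - k))
    lo = 1.0 / (1.0 + np.exp(-(logit - z * se)))
    hi = 1.0 / (1.0 + np.exp(-(logit + z * se)))
    if at_lower:
        lo = 0.0
    if at_upper:
        hi = 1.0
    return point, float(lo), float(hi)


def logit2(p):
    """log2 odds: ``log2(p / (1 - p))``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("proportions must lie strictly inside (0, 1)")
    out = np.log2(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def _corrected_proportions(clumpy: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Proportions with a half-count correction applied only at the boundaries."""
    clumpy = np.asarray(clumpy, dtype=float)
    total = np.asarray(total, dtype=float)
    p = clumpy / total
    boundary = (clumpy == 0) | (clumpy == total)
    p = np.where(boundary, (clumpy + 0.5) / (total + 1.0), p)
    return p


def logit2_trajectory(series: CompetitionTimeSeries, boundary_correction: bool = True) -> list[tuple[float, float]]:
    """Log2-odds values rescaled so each trajectory starts at exactly 0.

    The rescaling subtracts the trajectory's value at its earliest time point.
    """
    if boundary_correction:
        p = _corrected_proportions(series.clumpy_counts, series.total_counts)
    else:
        p = series.proportions
    values = logit2(p)
    values = np.atleast_1d(values)
    out = np.empty_like(values)
    for tid in np.unique(series.trajectory_ids):
        mask = series.trajectory_ids == tid
        t0_idx = np.flatnonzero(mask)[np.argmin(series.times_days[mask])]
        out[mask] = values[mask] - values[t0_idx]
    return list(zip(series.times_days.tolist(), out.tolist()))


def _pooled_slopes(times: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slope of y against times for each row of y (vectorised)."""
    t = times - times.mean()
    denom = np.sum(t**2)
    if denom == 0:
        raise EstimationError("all time points identical; slope undefined")
    yc = y - y.mean(axis=-1, keepdims=True)
    return yc @ t / denom


def selection_coefficient(
    series: CompetitionTimeSeries,
    n_resamples: int = 500,
    seed: int | None = None,
    per_replicate: bool = False,
):
    """Mean least-squares slope of resampled logit2-rescaled trajectories.

    Each resample redraws every observation's clumpy count binomially at its
    observed proportion and total, rescales each trajectory to its own t=0 on
    the log2-odds scale, and fits a pooled least-squares slope against time in
    days.  The mean of the slopes is the point estimate, their SD the standard
    error, and the 95% CI is +/- 1.96 SE.  With ``per_replicate=True`` a dict of
    per-trajectory estimates is returned instead of the pooled one.
    """
    if np.unique(series.times_days).size < 2:
        raise EstimationError("need >= 2 distinct time points")
    if per_replicate:
        out = {}
        for tid in np.unique(series.trajectory_ids):
            mask = series.trajectory_ids == tid
            sub = CompetitionTimeSeries(
                label=series.label,
                regime=series.regime,
                times_days=series.times_days[mask],
                clumpy_counts=series.clumpy_counts[mask],
                total_counts=series.total_counts[mask],
            )
            out[tid] = selection_coefficient(sub, n_resamples=n_resamples, seed=seed)
        return out

    rng = np.random.default_rng(seed)
    p_obs = series.proportions
    totals = series.total_counts
    # (n_resamples, n_obs) redrawn counts at the observed proportions and totals
    draws = rng.binomial(totals[None, :], p_obs[None, :], size=(n_resamples, totals.size))
    p = _corrected_proportions(draws, totals[None, :])
    values = np.log2(p / (1.0 - p))
    rescaled = np.empty_like(values)
    for tid in np.unique(series.trajectory_ids):
        mask = series.trajectory_ids == tid
        t0_idx = np.flatnonzero(mask)[np.argmin(series.times_days[mask])]
        rescaled[:, mask] = values[:, mask] - values[:, [t0_idx]]
    slopes = _pooled_slopes(series.times_days, rescaled)
    point = float(slopes.mean())
    se = float(slopes.std(ddof=1)) if n_resamples > 1 else 0.0
    ci = (point - _Z95 * se, point + _Z95 * se)
    if se > 0:
        p_value = float(2.0 * norm.sf(abs(point) / se))
    else:
        p_value = 0.0 if point != 0 else 1.0
    return SelectionEstimate(
        coefficient=point,
        standard_error=se,
        ci95=ci,
        p_value=p_value,
        n_resamples=n_resamples,
        seed=seed,
        slopes=slopes,
    )


def proportion_summary(category_counts) -> list[tuple[str, float]]:
    """Percent share of each category, reported to one decimal place.

    ``category_counts`` is a list of (label, count) pairs or a mapping.
    """
    items = list(category_counts.items()) if hasattr(category_counts, "items") else list(category_counts)
    if not items:
        raise InputError("empty input")
    counts = np.array([c for _, c in items], dtype=float)
    if np.any(counts < 0):
        raise InputError("counts must be >= 0")
    total = counts.sum()
    if total <= 0:
        raise InputError("total count must be > 0")
    return [(label, round(100.0 * c / total, 1)) for (label, _), c in zip(items, counts)]
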