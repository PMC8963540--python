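"""Arbitrary-unit sedimentation rates from OD600 decay traces.

The assay records absorbance every 30 s for 3 min while cells settle out of
the light path.  The settling rate in arbitrary units per second is the
proportional decay rate of the OD signal, which is invariant to uniform
dilution of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError

__all__ = ["ODTimeSeries", "SedimentationRateAU", "decay_rate_from_od"]


@dataclass
class ODTimeSeries:
    """One OD600 trace: strictly increasing times (s) and positive absorbances."""

    times: np.ndarray
    od_values: np.ndarray
    dilution_factor: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_values = np.asarray(self.od_values, dtype=float)
        if self.times.size != self.od_values.size:
            raise InputError("times and od_values must have equal length")
        if self.times.size < 2:
            raise InputError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(self.od_values <= 0):
            raise DomainError("all OD values must be > 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class SedimentationRateAU:
    """Proportional OD decay rate, in arbitrary units per second."""

    rate: float
    method: str
    metadata: dict = field(default_factory=dict)


def decay_rate_from_od(series: ODTimeSeries, method: str = "endpoint") -> SedimentationRateAU:
    """Decay rate of an OD trace assuming constant proportional change.

    ``endpoint`` uses the first and last points: ``-ln(OD_last/OD_first) / (t_last - t_first)``.
    ``log_linear`` uses the negated least-squares slope of ln(OD) against time,
    which uses all recorded points.  Both agree exactly on 2-point series and
    are invariant to scaling all OD values by a constant (dilution).
    """
    t, od = series.times, series.od_values
    if method == "endpoint":
        rate = -np.log(od[-1] / od[0]) / (t[-1] - t[0])
    elif method == "log_linear":
        slope = np.polyfit(t, np.log(od), 1)[0]
        rate = -slope
    else:
        raise InputError(f"unknown method {method!r}; use 'endpoint' or 'log_linear'")
    return SedimentationRateAU(rate=float(rate), method=method, metadata=dict(series.metadata))
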