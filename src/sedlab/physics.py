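"""Closed-form Stokes'-law physics, spherical geometry, and the seawater density model.

Everything in this module is deterministic and unit-strict: lengths in meters,
velocities in m/s, densities in kg/m^3, salinity in g/L, temperature in degrees
Celsius.  Array inputs broadcast; scalars come back as floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DomainError, FitError, StateError

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "Medium",
    "SphereGeometry",
    "SeawaterDensityModel",
    "DensityInversion",
    "radius_from_perimeter",
    "volume_from_radius",
    "stokes_velocity",
    "excess_density_from_velocity",
    "fit_seawater_density_model",
    "predict_seawater_density",
    "absolute_salinity",
    "FRESHWATER_DENSITY",
]

#: Density of distilled water; excess densities are reported relative to this.
FRESHWATER_DENSITY = 1000.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physics of the settling assay.

    ``stokes_prefactor`` is 2*g/(9*mu) so that ``v = prefactor * excess_density * R**2``.
    """

    dynamic_viscosity: float = 0.00109  # Pa*s
    gravitational_acceleration: float = 9.780  # m/s^2
    salinity_constant: float = 35.16504 / 35.0  # dimensionless

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0:
            raise DomainError("dynamic_viscosity must be > 0")
        if self.gravitational_acceleration <= 0:
            raise DomainError("gravitational_acceleration must be > 0")

    @property
    def stokes_prefactor(self) -> float:
        return 2.0 * self.gravitational_acceleration / (9.0 * self.dynamic_viscosity)


#: Module-level default constants.
CONSTANTS = PhysicalConstants()


@dataclass
class Medium:
    """A liquid medium characterised by salinity (g/L) and temperature (degC)."""

    salinity: float
    temperature: float
    density: float | None = None  # kg/m^3, optional until predicted

    def __post_init__(self) -> None:
        if self.salinity < 0:
            raise DomainError("salinity must be >= 0")
        if self.density is not None and not (900.0 < self.density < 1100.0):
            raise DomainError(
                f"medium density {self.density} kg/m^3 outside plausible (900, 1100) range"
            )


@dataclass(frozen=True)
class SphereGeometry:
    """Radius and volume of a sphere derived from a perimeter measurement."""

    perimeter: float
    radius: float = field(init=False)
    volume: float = field(init=False)

    def __post_init__(self) -> None:
        r = radius_from_perimeter(self.perimeter)
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "volume", volume_from_radius(r))


def radius_from_perimeter(perimeter):
    """Radius of a sphere from its great-circle perimeter: ``P / (2*pi)``."""
    p = np.asarray(perimeter, dtype=float)
    if np.any(p <= 0):
        raise DomainError("perimeter must be > 0")
    out = p / (2.0 * np.pi)
    return float(out) if np.isscalar(perimeter) or out.ndim == 0 else out


def volume_from_radius(radius):
    """Sphere volume ``(4/3)*pi*r**3``."""
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise DomainError("radius must be > 0")
    out = (4.0 / 3.0) * np.pi * r**3
    return float(out) if np.isscalar(radius) or out.ndim == 0 else out


def stokes_velocity(excess_density, radius, constants: PhysicalConstants = CONSTANTS):
    """Terminal settling velocity of a small sphere: ``2*g*R^2*drho / (9*mu)``.

    ``excess_density`` is the particle density minus the fluid density (kg/m^3);
    a negative value yields a negative (buoyant rise) velocity.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise DomainError("radius must be > 0")
    drho = np.asarray(excess_density, dtype=float)
    out = constants.stokes_prefactor * drho * r**2
    if np.isscalar(excess_density) and np.isscalar(radius):
        return float(out)
    return out


class DensityInversion(NamedTuple):
    """Result of inverting Stokes' law for particle density."""

    particle_density: float  # kg/m^3
    excess_density: float  # relative to distilled water (1000 kg/m^3)


def excess_density_from_velocity(
    velocity,
    radius,
    medium_density,
    constants: PhysicalConstants = CONSTANTS,
) -> DensityInversion:
    """Invert Stokes' law: ``p_p = p_f + 9*mu*V / (2*g*R^2)``.

    Returns both the particle density and its excess over distilled water
    (1000 kg/m^3).  Exact inverse of :func:`stokes_velocity`.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise DomainError("radius must be > 0")
    v = np.asarray(velocity, dtype=float)
    pf = np.asarray(medium_density, dtype=float)
    pp = pf + v / (constants.stokes_prefactor * r**2)
    excess = pp - FRESHWATER_DENSITY
    if pp.ndim == 0:
        return DensityInversion(float(pp), float(excess))
    return DensityInversion(pp, excess)


def absolute_salinity(practical_salinity, constants: PhysicalConstants = CONSTANTS):
    """Scale a practical salinity (g/L) by the reference-composition constant.

    The constant is the dimensionless ratio 35.16504/35, so 35 g/L maps to
    35.16504 g/kg.  This is a bookkeeping conversion; the polynomial density
    model is the operative density source.
    """
    s = np.asarray(practical_salinity, dtype=float)
    if np.any(s < 0):
        raise DomainError("salinity must be >= 0")
    out = constants.salinity_constant * s
    return float(out) if np.isscalar(practical_salinity) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Seawater density as a quadratic surface in (salinity, temperature)
# ---------------------------------------------------------------------------


def _design_matrix(salinity: np.ndarray, temperature: np.ndarray) -> np.ndarray:
    s = np.asarray(salinity, dtype=float).ravel()
    t = np.asarray(temperature, dtype=float).ravel()
    return np.column_stack([np.ones_like(s), s, t, s**2, t**2, s * t])


@dataclass
class SeawaterDensityModel:
    """Full quadratic surface rho(salinity, temperature) fitted by least squares.

    ``coefficients`` are ordered (intercept, S, T, S^2, T^2, S*T).
    """

    coefficients: np.ndarray | None = None
    fit_residual_max: float | None = None
    salinity_range: tuple[float, float] | None = None
    temperature_range: tuple[float, float] | None = None

    @property
    def is_fitted(self) -> bool:
        return self.coefficients is not None

    def predict(self, salinity, temperature):
        """Evaluate the fitted surface; warns outside 10% beyond the training hull."""
        if not self.is_fitted:
            raise StateError("SeawaterDensityModel is not fitted")
        s = np.asarray(salinity, dtype=float)
        t = np.asarray(temperature, dtype=float)
        self._warn_if_extrapolating(s, t)
        x = _design_matrix(s, t)
        out = x @ self.coefficients
        if s.ndim == 0 and t.ndim == 0:
            return float(out[0])
        return out.reshape(np.broadcast(s, t).shape)

    def _warn_if_extrapolating(self, s: np.ndarray, t: np.ndarray) -> None:
        for value, rng, name in ((s, self.salinity_range, "salinity"), (t, self.temperature_range, "temperature")):
            if rng is None:
                continue
            lo, hi = rng
            span = max(hi - lo, 1e-12)
            if np.any(value < lo - 0.1 * span) or np.any(value > hi + 0.1 * span):
                warnings.warn(
                    f"{name} outside 10% beyond the training range [{lo}, {hi}]; "
                    "extrapolated densities may be unreliable",
                    stacklevel=3,
                )


def fit_seawater_density_model(reference_rows) -> SeawaterDensityModel:
    """Least-squares fit of the quadratic density surface.

    ``reference_rows`` is an iterable of (temperature_degC, salinity_gL,
    density_kgm3) triples, or an (n, 3) array in that column order.
    Requires at least 6 rows spanning >= 2 distinct temperatures and
    salinities and a full-rank design.
    """
    rows = np.asarray(list(reference_rows), dtype=float)
    if rows.ndim != 2 or rows.shape[1] != 3:
        raise FitError("expected rows of (temperature, salinity, density)")
    if rows.shape[0] < 6:
        raise FitError(f"need >= 6 rows to fit 6 coefficients, got {rows.shape[0]}")
    temp, sal, dens = rows[:, 0], rows[:, 1], rows[:, 2]
    if np.unique(temp).size < 2 or np.unique(sal).size < 2:
        raise FitError("need >= 2 distinct temperatures and >= 2 distinct salinities")
    x = _design_matrix(sal, temp)
    if np.linalg.matrix_rank(x) < 6:
        raise FitError("rank-deficient design: covariates do not span a quadratic surface")
    coef, *_ = np.linalg.lstsq(x, dens, rcond=None)
    resid = dens - x @ coef
    return SeawaterDensityModel(
        coefficients=coef,
        fit_residual_max=float(np.max(np.abs(resid))),
        salinity_range=(float(sal.min()), float(sal.max())),
        temperature_range=(float(temp.min()), float(temp.max())),
    )


def predict_seawater_density(model: SeawaterDensityModel, salinity, temperature):
    """Functional alias for :meth:`SeawaterDensityModel.predict`."""
    return model.predict(salinity, temperature)
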