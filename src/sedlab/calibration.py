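"""Joint calibration of AU settling rates against a reference settling compilation.

Two parameters are fitted by least squares: a log-scalar ``S`` that converts
arbitrary-unit assay rates into m/s via ``exp(S)``, and a single common excess
density ``p_p_hat`` (kg/m^3) shared by every observation.  Reference rows enter
with their expected velocity in the assay medium (indicator H = 0); assay rows
enter with their raw AU rate (H = 1).  The loss is

    sum_i (V0_i * exp(S * H_i) - prefactor * p_p_hat * R_i**2) ** 2

with ``prefactor = 2*g/(9*mu)``.  Uncertainty comes from repeated refits on
random 90% subsets of the rows ("out-of-bag" bootstrap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DomainError, FitError, InputError, StateError
from .physics import (
    CONSTANTS,
    PhysicalConstants,
    SeawaterDensityModel,
    excess_density_from_velocity,
    stokes_velocity,
)

__all__ = [
    "ASSAY_MEDIUM_DENSITY",
    "CELLULOSE_EXCESS_DENSITY",
    "ReferenceObservation",
    "CalibrationObservations",
    "CalibrationFit",
    "DensityEstimate",
    "prepare_reference",
    "calibration_loss",
    "fit_calibration",
    "bootstrap_calibration",
    "estimate_velocity_density",
]

logger = logging.getLogger(__name__)

#: Density of the assay growth medium (37.4 g/L formulation), kg/m^3.
ASSAY_MEDIUM_DENSITY = 1028.9

#: Excess density of pure cellulose, kg/m^3; reference rows above it are outliers.
CELLULOSE_EXCESS_DENSITY = 500.0

#: Taxon excluded for anomalously low settling given its size.
_EXCLUDED_TAXON_FRAGMENT = "rex"

_DEFAULT_BOUNDS = ((-10.0, 10.0), (1.0, 1500.0))


@dataclass
class ReferenceObservation:
    """One row of the reference settling compilation after preparation."""

    taxon_label: str
    salinity: float  # g/L
    temperature: float | None  # degC; None if the table carries Pf directly
    measured_velocity: float  # m/s in the original medium
    media_density: float  # p_f, kg/m^3
    radius: float  # m
    particle_density: float  # p_p, kg/m^3 (Stokes inversion)
    excess_density: float  # p_p - 1000, kg/m^3
    expected_assay_velocity: float | None  # V_exp in the assay medium; None if excluded
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class CalibrationObservations:
    """Stacked arrays feeding the joint loss: V0, radius, and the study indicator H."""

    v0: np.ndarray
    radius: np.ndarray
    is_study: np.ndarray

    def __post_init__(self) -> None:
        self.v0 = np.asarray(self.v0, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.is_study = np.asarray(self.is_study, dtype=float)
        if not (self.v0.size == self.radius.size == self.is_study.size):
            raise InputError("v0, radius, is_study must have equal length")
        if self.v0.size == 0:
            raise InputError("observations are empty")
        if np.any(self.radius <= 0):
            raise DomainError("all radii must be > 0")

    def __len__(self) -> int:
        return int(self.v0.size)

    def subset(self, idx) -> "CalibrationObservations":
        return CalibrationObservations(self.v0[idx], self.radius[idx], self.is_study[idx])

    @classmethod
    def from_tables(cls, reference: list[ReferenceObservation], assay: pd.DataFrame) -> "CalibrationObservations":
        """Stack retained reference rows (H=0, V0=V_exp) and assay rows (H=1, V0=V_au)."""
        ref = [r for r in reference if not r.excluded]
        v0 = np.concatenate(
            [
                np.array([r.expected_assay_velocity for r in ref], dtype=float),
                assay["V_au"].to_numpy(dtype=float),
            ]
        )
        radius = np.concatenate(
            [
                np.array([r.radius for r in ref], dtype=float),
                assay["R_meters"].to_numpy(dtype=float),
            ]
        )
        h = np.concatenate([np.zeros(len(ref)), np.ones(len(assay))])
        return cls(v0, radius, h)


def prepare_reference(
    raw_rows: pd.DataFrame,
    seawater_model: SeawaterDensityModel | None = None,
    constants: PhysicalConstants = CONSTANTS,
    assay_medium_density: float = ASSAY_MEDIUM_DENSITY,
) -> list[ReferenceObservation]:
    """Compute media/particle densities for the reference compilation and flag outliers.

    Accepts either ``salt_percent`` (percent by mass, multiplied by 10 to g/L)
    or ``salinity`` (g/L) for the salt content.  Media density is predicted
    from the seawater model when a temperature column (``temp_C`` or ``temp``)
    is present, and taken from a ``Pf`` column otherwise.  Rows with excess
    density above cellulose (500 kg/m^3) or belonging to the anomalous
    large-diatom taxon are flagged excluded; the rest get ``V_exp``, the Stokes
    velocity each particle would have in the assay medium.
    """
    df = raw_rows
    if "salinity" in df.columns:
        salinity = df["salinity"].to_numpy(dtype=float)
    elif "salt_percent" in df.columns:
        salinity = df["salt_percent"].to_numpy(dtype=float) * 10.0
    else:
        raise InputError("reference table needs a 'salt_percent' or 'salinity' column")
    for col in ("V_meters_per_second", "R_meters"):
        if col not in df.columns:
            raise InputError(f"reference table is missing required column {col!r}")

    temp_col = next((c for c in ("temp_C", "temp") if c in df.columns), None)
    if temp_col is not None and seawater_model is not None:
        temperature = df[temp_col].to_numpy(dtype=float)
        media_density = np.asarray(seawater_model.predict(salinity, temperature), dtype=float)
        media_density = np.atleast_1d(media_density)
    elif "Pf" in df.columns:
        temperature = df[temp_col].to_numpy(dtype=float) if temp_col else np.full(len(df), np.nan)
        media_density = df["Pf"].to_numpy(dtype=float)
    else:
        raise InputError(
            "cannot determine media density: provide a temperature column with a "
            "seawater model, or a precomputed 'Pf' column"
        )

    velocity = df["V_meters_per_second"].to_numpy(dtype=float)
    radius = df["R_meters"].to_numpy(dtype=float)
    labels = (
        df["classification"].astype(str).to_numpy()
        if "classification" in df.columns
        else np.array([f"row{i}" for i in range(len(df))])
    )

    out: list[ReferenceObservation] = []
    for i in range(len(df)):
        pp, excess = excess_density_from_velocity(velocity[i], radius[i], media_density[i], constants)
        excluded, reason = False, None
        if excess > CELLULOSE_EXCESS_DENSITY:
            excluded, reason = True, "excess density above cellulose"
        elif _EXCLUDED_TAXON_FRAGMENT in labels[i].lower():
            excluded, reason = True, "taxon exclusion"
        v_exp = None if excluded else stokes_velocity(pp - assay_medium_density, radius[i], constants)
        out.append(
            ReferenceObservation(
                taxon_label=labels[i],
                salinity=float(salinity[i]),
                temperature=None if np.isnan(temperature[i]) else float(temperature[i]),
                measured_velocity=float(velocity[i]),
                media_density=float(media_density[i]),
                radius=float(radius[i]),
                particle_density=float(pp),
                excess_density=float(excess),
                expected_assay_velocity=v_exp,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    n_excluded = sum(r.excluded for r in out)
    if n_excluded:
        logger.info("prepare_reference: excluded %d of %d rows", n_excluded, len(out))
    return out


def calibration_loss(s, p_p_hat, observations: CalibrationObservations, constants: PhysicalConstants = CONSTANTS) -> float:
    """Sum of squared differences between (scaled) observed and Stokes-predicted velocities."""
    resid = _residuals(s, p_p_hat, observations, constants)
    return float(np.sum(resid**2))


def _residuals(s, p_p_hat, obs: CalibrationObservations, constants: PhysicalConstants) -> np.ndarray:
    predicted = constants.stokes_prefactor * p_p_hat * obs.radius**2
    return obs.v0 * np.exp(s * obs.is_study) - predicted


def fit_calibration(
    observations: CalibrationObservations,
    constants: PhysicalConstants = CONSTANTS,
    init_s: float = 0.03,
    init_pp: float = 100.0,
    bounds=_DEFAULT_BOUNDS,
) -> tuple[float, float]:
    """Bounded quasi-Newton (L-BFGS-B) minimisation of :func:`calibration_loss`.

    Deterministic given its inputs.  The loss is internally rescaled to unit
    magnitude so the optimiser's stopping rules behave for micrometer-scale
    velocities; the rescaling does not move the minimum.
    """
    if len(observations) < 2:
        raise InputError("need at least 2 observations")
    if observations.is_study.sum() < 1 or (1 - observations.is_study).sum() < 1:
        raise InputError("need at least 1 study row and 1 reference row")

    scale = 1.0 / max(float(np.max(np.abs(observations.v0))) ** 2, 1e-300)

    def fun(x):
        r = _residuals(x[0], x[1], observations, constants)
        loss = scale * np.sum(r**2)
        pred_grad = constants.stokes_prefactor * observations.radius**2
        g_s = scale * np.sum(2 * r * observations.v0 * observations.is_study * np.exp(x[0] * observations.is_study))
        g_pp = scale * np.sum(-2 * r * pred_grad)
        return loss, np.array([g_s, g_pp])

    res = minimize(
        fun,
        x0=np.array([init_s, init_pp]),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-14},
    )
    if not res.success and res.status != 2:  # status 2: ftol/xtol convergence edge
        raise FitError(
            f"calibration fit did not converge: {res.message} "
            f"(loss={res.fun / scale:.3e}, |grad|={np.linalg.norm(res.jac):.3e})"
        )
    return float(res.x[0]), float(res.x[1])


@dataclass
class CalibrationFit:
    """Bootstrap summary of the joint calibration."""

    S: float
    p_p_hat: float
    S_se: float
    p_p_hat_se: float
    fold_estimates: np.ndarray  # (n_reps, 2) columns (S, p_p_hat)
    fold_correlation: float
    seed: int | None
    holdout_indices: list = field(default_factory=list, repr=False)
    n_degenerate_redraws: int = 0

    @property
    def n_reps(self) -> int:
        return int(self.fold_estimates.shape[0])


def bootstrap_calibration(
    observations: CalibrationObservations,
    constants: PhysicalConstants = CONSTANTS,
    n_reps: int = 500,
    holdout_fraction: float = 0.10,
    seed: int | None = None,
    init_s: float = 0.03,
    init_pp: float = 100.0,
    bounds=_DEFAULT_BOUNDS,
) -> CalibrationFit:
    """Refit the calibration on ``n_reps`` random (1 - holdout_fraction) subsets.

    Reports the mean of the fold estimates as the point estimate and their SD
    as the standard error, plus the Pearson correlation between the two
    parameters across folds.  Degenerate subsets (missing either stratum) are
    redrawn and counted.  Fully reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = len(observations)
    n_train = max(int(round((1.0 - holdout_fraction) * n)), 2)
    estimates = np.empty((n_reps, 2))
    holdouts: list[np.ndarray] = []
    n_redraws = 0
    for rep in range(n_reps):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            train, held = perm[:n_train], perm[n_train:]
            h_train = observations.is_study[train]
            if h_train.sum() >= 1 and (1 - h_train).sum() >= 1:
                break
            n_redraws += 1
        else:
            raise FitError("could not draw a training subset containing both strata")
        s_hat, pp_hat = fit_calibration(
            observations.subset(train), constants, init_s=init_s, init_pp=init_pp, bounds=bounds
        )
        estimates[rep] = (s_hat, pp_hat)
        holdouts.append(np.sort(held))
    if n_redraws:
        logger.info("bootstrap_calibration: %d degenerate subsets redrawn", n_redraws)
    sd = estimates.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(2)
    if n_reps > 1 and sd[0] > 0 and sd[1] > 0:
        corr = float(np.corrcoef(estimates[:, 0], estimates[:, 1])[0, 1])
    else:
        corr = np.nan
    return CalibrationFit(
        S=float(estimates[:, 0].mean()),
        p_p_hat=float(estimates[:, 1].mean()),
        S_se=float(sd[0]),
        p_p_hat_se=float(sd[1]),
        fold_estimates=estimates,
        fold_correlation=corr,
        seed=seed,
        holdout_indices=holdouts,
        n_degenerate_redraws=n_redraws,
    )


@dataclass(frozen=True)
class DensityEstimate:
    """Group-level velocity and density estimate with bootstrap spread."""

    V_mu: float
    V_se: float
    pp_mu: float
    pp_se: float
    n_rows: int


def estimate_velocity_density(
    fit: CalibrationFit,
    rate_au,
    radius: float,
    medium_density: float = ASSAY_MEDIUM_DENSITY,
    constants: PhysicalConstants = CONSTANTS,
) -> DensityEstimate:
    """Convert a group of AU rates to physical velocity and density per bootstrap fold.

    For each fold, the group's mean AU rate is scaled by ``exp(S_fold)`` to a
    velocity in m/s, then Stokes-inverted at the group's (shared mean) radius.
    Means and SDs across folds are reported.
    """
    if fit.fold_estimates.size == 0:
        raise StateError("CalibrationFit has no fold estimates")
    rates = np.atleast_1d(np.asarray(rate_au, dtype=float))
    if rates.size == 0:
        raise InputError("group is empty")
    if radius <= 0:
        raise DomainError("radius must be > 0")
    mean_rate = float(rates.mean())
    s_folds = fit.fold_estimates[:, 0]
    v_folds = mean_rate * np.exp(s_folds)
    pp_folds = medium_density + v_folds / (constants.stokes_prefactor * radius**2)
    ddof = 1 if v_folds.size > 1 else 0
    return DensityEstimate(
        V_mu=float(v_folds.mean()),
        V_se=float(v_folds.std(ddof=ddof)),
        pp_mu=float(pp_folds.mean()),
        pp_se=float(pp_folds.std(ddof=ddof)),
        n_rows=int(rates.size),
    )


def calibrate_assay_table(
    assay: pd.DataFrame,
    fit: CalibrationFit,
    medium_density: float = ASSAY_MEDIUM_DENSITY,
    constants: PhysicalConstants = CONSTANTS,
    group_cols: tuple[str, ...] = ("species", "genotype", "temp", "hours_growth"),
) -> pd.DataFrame:
    """Append V_mu/V_se/pp_mu/pp_se columns to an assay table, per group.

    Grouping follows the assay schema's genotype/environment columns; each
    group uses its mean radius.
    """
    cols = [c for c in group_cols if c in assay.columns]
    out = assay.copy()
    for col in ("V_mu", "V_se", "pp_mu", "pp_se"):
        out[col] = np.nan
    grouped = out.groupby(list(cols), dropna=False, sort=False) if cols else [(None, out)]
    for _key, grp in grouped:
        est = estimate_velocity_density(
            fit,
            grp["V_au"].to_numpy(dtype=float),
            float(grp["R_meters"].astype(float).mean()),
            medium_density=medium_density,
            constants=constants,
        )
        out.loc[grp.index, ["V_mu", "V_se", "pp_mu", "pp_se"]] = (est.V_mu, est.V_se, est.pp_mu, est.pp_se)
    return out
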