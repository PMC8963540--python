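"""Seed-deterministic generators for every input table, with ground truth sidecars.

Each generator returns ``(table, truth)`` where ``truth`` is a plain dict of
the parameters the table was built from, so every analysis stage has a
parameter-recovery test without external downloads.  Noise models respect each
quantity's support: lognormal multiplicative for velocities and OD,
binomial/multinomial for counts, Gaussian for phenotypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .physics import CONSTANTS, PhysicalConstants, stokes_velocity
from .calibration import ASSAY_MEDIUM_DENSITY

__all__ = [
    "SEAWATER_TRUTH_COEFFICIENTS",
    "true_seawater_density",
    "gen_seawater_table",
    "gen_reference_table",
    "gen_od_assay",
    "gen_competition",
    "gen_nuclei_timecourse",
    "gen_phenotype_table",
    "write_with_truth",
]

#: Quadratic surface used as ground truth for synthetic seawater densities:
#: (intercept, S, T, S^2, T^2, S*T) with S in g/L, T in degC, rho in kg/m^3.
SEAWATER_TRUTH_COEFFICIENTS = np.array([999.70, 0.78, 0.02, 4.0e-4, -4.5e-3, -3.0e-4])


def true_seawater_density(salinity, temperature):
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    b = SEAWATER_TRUTH_COEFFICIENTS
    return b[0] + b[1] * s + b[2] * t + b[3] * s**2 + b[4] * t**2 + b[5] * s * t


def gen_seawater_table(seed: int | None = None, noise_sd: float = 0.0) -> tuple[pd.DataFrame, dict]:
    """Density reference grid over salinity 5-70 g/L and temperature 0-40 degC."""
    rng = np.random.default_rng(seed)
    sal = np.repeat(np.linspace(5.0, 70.0, 14), 9)
    temp = np.tile(np.linspace(0.0, 40.0, 9), 14)
    dens = true_seawater_density(sal, temp)
    if noise_sd > 0:
        dens = dens + rng.normal(0.0, noise_sd, size=dens.size)
    df = pd.DataFrame(
        {
            "temp_C": temp,
            "salinity": sal,
            "density_kgm3": dens - 1000.0,
            "density": dens,
        }
    )
    truth = {
        "seed": seed,
        "noise_sd": noise_sd,
        "coefficients": SEAWATER_TRUTH_COEFFICIENTS.tolist(),
    }
    return df, truth


def gen_reference_table(
    n: int = 39,
    seed: int | None = None,
    noise_cv: float = 0.0,
    excess_density_range: tuple[float, float] = (30.0, 480.0),
    radius_range: tuple[float, float] = (2e-6, 3e-4),
    salinity_range: tuple[float, float] = (28.0, 40.0),
    temperature_range: tuple[float, float] = (2.0, 25.0),
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Settling compilation emulator: velocities built by Stokes' law from sampled truth.

    With ``noise_cv = 0`` the Stokes inversion recovers the sampled particle
    densities exactly.
    """
    lo, hi = excess_density_range
    if not (0 < lo < hi <= 1500):
        raise ConfigError("excess_density_range must lie within (0, 1500]")
    if not (0 < radius_range[0] < radius_range[1]):
        raise ConfigError("invalid radius_range")
    rng = np.random.default_rng(seed)
    excess = rng.uniform(lo, hi, size=n)  # over distilled water
    radius = np.exp(rng.uniform(np.log(radius_range[0]), np.log(radius_range[1]), size=n))
    salinity = rng.uniform(*salinity_range, size=n)
    temperature = rng.uniform(*temperature_range, size=n)
    pf = true_seawater_density(salinity, temperature)
    pp = 1000.0 + excess
    v = stokes_velocity(pp - pf, radius, constants)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        v = v * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    v_exp = stokes_velocity(pp - ASSAY_MEDIUM_DENSITY, radius, constants)
    df = pd.DataFrame(
        {
            "classification": [f"synthetic sp. {i:02d}" for i in range(n)],
            "salt_percent": salinity / 10.0,
            "temp_C": temperature,
            "V_meters_per_second": v,
            "Pf": pf,
            "R_meters": radius,
            "Pp_": pp,
            "Pp": pp - 1000.0,
            "V_exp": v_exp,
        }
    )
    truth = {
        "seed": seed,
        "noise_cv": noise_cv,
        "excess_density": excess.tolist(),
        "radius": radius.tolist(),
        "media_density": pf.tolist(),
    }
    return df, truth


def gen_od_assay(
    n_series: int = 20,
    seed: int | None = None,
    s_true: float = 0.03,
    true_velocities=None,
    velocity_range: tuple[float, float] = (1e-6, 1.2e-4),
    radius_range: tuple[float, float] = (1e-5, 1e-4),
    od0: float = 0.5,
    noise_cv: float = 0.0,
    times=None,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """OD600 decay traces whose AU decay rate times exp(s_true) is the true velocity.

    Seven points at 30 s spacing over 3 minutes by default.  With
    ``noise_cv = 0`` the round trip through the decay-rate estimator and the
    scaling recovers the true velocities exactly.
    """
    if od0 <= 0:
        raise ConfigError("od0 must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 181.0, 30.0) if times is None else np.asarray(times, dtype=float)
    if true_velocities is None:
        v_true = np.exp(rng.uniform(np.log(velocity_range[0]), np.log(velocity_range[1]), size=n_series))
    else:
        v_true = np.asarray(true_velocities, dtype=float)
        n_series = v_true.size
    radius = np.exp(rng.uniform(np.log(radius_range[0]), np.log(radius_range[1]), size=n_series))
    k = v_true / np.exp(s_true)  # AU/s decay rate
    rows = []
    for i in range(n_series):
        od = od0 * np.exp(-k[i] * t)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            od = od * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
        for tj, oj in zip(t, od):
            rows.append(
                {
                    "series_id": i,
                    "time_s": tj,
                    "od600": oj,
                    "species": "synthetic",
                    "genotype": f"g{i:02d}",
                    "temp": 17.0,
                    "hours_growth": 24.0,
                    "R_meters": radius[i],
                }
            )
    df = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "s_true": s_true,
        "noise_cv": noise_cv,
        "velocity": v_true.tolist(),
        "decay_rate_au": k.tolist(),
        "radius": radius.tolist(),
    }
    return df, truth


def gen_competition(
    seed: int | None = None,
    s_true: float = 0.23,
    p0: float = 0.5,
    n_per_day: int = 200,
    days=(0.0, 1.0, 2.0, 3.0),
    n_replicates: int = 2,
    genotype: str = "SYN",
    regime: str = "YES_SEL",
) -> tuple[pd.DataFrame, dict]:
    """Binomially sampled logistic competition trajectories with log2-odds slope ``s_true``."""
    if not 0 < p0 < 1:
        raise ConfigError("p0 must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    l0 = np.log2(p0 / (1.0 - p0))
    p_t = 1.0 / (1.0 + 2.0 ** (-(l0 + s_true * days)))
    rows = []
    for rep in range(n_replicates):
        clumpy = rng.binomial(n_per_day, p_t)
        for d, k, pt in zip(days, clumpy, p_t):
            rows.append(
                {
                    "batch": "D",
                    "rep": f"rep{rep + 1}",
                    "geno": genotype,
                    "time": d * 24.0,  # hours in file
                    "sel_cond": regime,
                    "NOT_CLUMPY": int(n_per_day - k),
                    "YES_CLUMPY": int(k),
                    "cell_density": np.nan,
                    "N": n_per_day,
                    "gen": np.nan,
                    "date": "synthetic",
                    "temp": 17.0,
                }
            )
    df = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "s_true": s_true,
        "p0": p0,
        "n_per_day": n_per_day,
        "p_t": p_t.tolist(),
    }
    return df, truth


def gen_nuclei_timecourse(
    seed: int | None = None,
    tau: float = 9.5,
    times=None,
    n_per_time: int | None = 500,
    base_log2: float = 0.0,
    max_ploidy: int = 256,
) -> tuple[pd.DataFrame, dict]:
    """Power-of-two ploidy distributions whose mean log2 content grows as t / tau.

    The mass at each time point is split between the two neighbouring
    power-of-two bins so the exact mean log2 ploidy is ``base_log2 + t/tau``;
    with ``n_per_time`` set, bin fractions are multinomially sampled.  Ploidy
    is capped at ``max_ploidy``.
    """
    if tau <= 0:
        raise ConfigError("tau must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 25.0, 4.0) if times is None else np.asarray(times, dtype=float)
    max_log2 = int(np.log2(max_ploidy))
    rows = []
    truth_bins = []
    for ti in t:
        m = min(base_log2 + ti / tau, float(max_log2))
        lower = int(np.floor(m))
        frac_up = m - lower
        probs = {2**lower: 1.0 - frac_up}
        if frac_up > 0 and lower + 1 <= max_log2:
            probs[2 ** (lower + 1)] = frac_up
        ploidies = sorted(probs)
        pvec = np.array([probs[x] for x in ploidies])
        if n_per_time is None:
            fracs = pvec
            n_cells = None
        else:
            counts = rng.multinomial(n_per_time, pvec)
            keep = counts > 0
            ploidies = [x for x, k in zip(ploidies, keep) if k]
            fracs = counts[keep] / n_per_time
            n_cells = n_per_time
        for x, f in zip(ploidies, fracs):
            rows.append({"time_h": ti, "ploidy": int(x), "fraction": float(f), "n_cells": n_cells})
        truth_bins.append({"time_h": float(ti), "mean_log2": m})
    df = pd.DataFrame(rows)
    truth = {"seed": seed, "tau": tau, "base_log2": base_log2, "bins": truth_bins}
    return df, truth


def gen_phenotype_table(
    seed: int | None = None,
    sigma2_g: float = 9.0,
    sigma2_e: float = 1.0,
    n_groups: int = 10,
    n_reps: int = 10,
    phenotype: str = "synthetic_trait",
) -> tuple[pd.DataFrame, dict]:
    """Genotype x environment phenotype table with known variance components."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ConfigError("variance components must be >= 0")
    if sigma2_g == 0 and sigma2_e == 0:
        raise ConfigError("at least one variance component must be positive")
    rng = np.random.default_rng(seed)
    group_means = rng.normal(0.0, np.sqrt(sigma2_g), size=n_groups)
    rows = []
    for g in range(n_groups):
        resid = rng.normal(0.0, np.sqrt(sigma2_e), size=n_reps)
        for r in range(n_reps):
            rows.append(
                {
                    "genotype": f"G{g:03d}",
                    "temp": 17.0,
                    "hours": 24.0,
                    "batch": f"b{r % 2}",
                    "phenotype": phenotype,
                    "value": group_means[g] + resid[r],
                }
            )
    df = pd.DataFrame(rows)
    expected_h = sigma2_g / (sigma2_g + sigma2_e) if sigma2_g + sigma2_e > 0 else None
    truth = {
        "seed": seed,
        "sigma2_g": sigma2_g,
        "sigma2_e": sigma2_e,
        "expected_H": expected_h,
        "group_means": group_means.tolist(),
    }
    return df, truth


def write_with_truth(df: pd.DataFrame, truth: dict, out_dir, name: str) -> tuple[Path, Path]:
    """Write a generated table as CSV plus its ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{name}.csv"
    truth_path = out / f"{name}.truth.json"
    df.to_csv(csv_path, index=False)
    truth_path.write_text(json.dumps(truth, indent=2))
    return csv_path, truth_path
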