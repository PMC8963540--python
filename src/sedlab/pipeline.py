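"""Pipeline orchestration: run configured stages end-to-end and write a manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationObservations,
    bootstrap_calibration,
    calibrate_assay_table,
    prepare_reference,
)
from .errors import ConfigError, StageError
from .fitness import CompetitionTimeSeries, selection_coefficient
from .growth import NucleiDistribution, nuclear_doubling_time
from .heritability import partition_variance
from .io import read_table, write_table
from .physics import CONSTANTS, fit_seawater_density_model

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "competition_series_from_table", "nuclei_series_from_table"]


@dataclass
class PipelineConfig:
    """Paths, seeds and knobs for a full pipeline run."""

    out_dir: Path
    assay_table: Path | None = None
    reference_table: Path | None = None
    seawater_table: Path | None = None
    competition_table: Path | None = None
    nuclei_table: Path | None = None
    phenotype_table: Path | None = None
    seed: int = 0
    n_bootstrap: int = 500
    n_resamples: int = 500
    log_phenotypes: tuple[str, ...] = ()
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in (
            "assay_table", "reference_table", "seawater_table",
            "competition_table", "nuclei_table", "phenotype_table",
        ):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if not self.stages:
            self.stages = tuple(self._infer_stages())
        self._validate()

    def _infer_stages(self):
        if self.assay_table and self.reference_table:
            yield "calibrate"
        if self.competition_table:
            yield "fitness"
        if self.nuclei_table:
            yield "doubling"
        if self.phenotype_table:
            yield "heritability"

    def _validate(self) -> None:
        requirements = {
            "calibrate": ("assay_table", "reference_table"),
            "fitness": ("competition_table",),
            "doubling": ("nuclei_table",),
            "heritability": ("phenotype_table",),
        }
        for stage in self.stages:
            if stage not in requirements:
                raise ConfigError(f"unknown stage {stage!r}")
            for attr in requirements[stage]:
                path = getattr(self, attr)
                if path is None:
                    raise ConfigError(f"stage {stage!r} requires {attr}")
                if not Path(path).exists():
                    raise ConfigError(f"stage {stage!r}: missing input file {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def competition_series_from_table(df: pd.DataFrame, genotype: str, regime: str) -> CompetitionTimeSeries:
    """Build a competition time series for one genotype/regime from an S4-schema table.

    File times are hours; slopes are per day, so times are divided by 24.
    Batch x rep pairs become separate trajectories.
    """
    sel = df[(df["geno"] == genotype) & (df["sel_cond"] == regime)]
    if sel.empty:
        raise ConfigError(f"no rows for geno={genotype!r}, sel_cond={regime!r}")
    tids = (sel["batch"].astype(str) + "/" + sel["rep"].astype(str)).to_numpy()
    return CompetitionTimeSeries(
        label=genotype,
        regime=regime,
        times_days=sel["time"].to_numpy(dtype=float) / 24.0,
        clumpy_counts=sel["YES_CLUMPY"].to_numpy(dtype=int),
        total_counts=(sel["YES_CLUMPY"] + sel["NOT_CLUMPY"]).to_numpy(dtype=int),
        trajectory_ids=tids,
    )


def nuclei_series_from_table(df: pd.DataFrame) -> list[NucleiDistribution]:
    """Group a pre-binned nuclei table (time_h, ploidy, fraction) into distributions."""
    series = []
    for t, grp in df.groupby("time_h", sort=True):
        n_cells = None
        if "n_cells" in grp.columns and grp["n_cells"].notna().any():
            n_cells = int(grp["n_cells"].dropna().iloc[0])
        fracs = grp["fraction"].to_numpy(dtype=float)
        series.append(
            NucleiDistribution(
                time=float(t),
                bins=[(int(p), float(f / fracs.sum())) for p, f in zip(grp["ploidy"], fracs)],
                n_cells=n_cells,
            )
        )
    return series


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write per-stage outputs plus a manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "warnings": [],
    }
    for attr in (
        "assay_table", "reference_table", "seawater_table",
        "competition_table", "nuclei_table", "phenotype_table",
    ):
        path = getattr(config, attr)
        if path is not None and Path(path).exists():
            manifest["inputs"][attr] = {"path": str(path), "sha256": _sha256(path)}

    for stage in config.stages:
        try:
            manifest["stages"][stage] = _STAGE_RUNNERS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_calibrate(config: PipelineConfig, out: Path) -> dict:
    assay = read_table(config.assay_table, "s1")
    reference = read_table(config.reference_table, "s2")
    seawater_model = None
    if config.seawater_table is not None:
        sw = read_table(config.seawater_table, "s3")
        seawater_model = fit_seawater_density_model(
            np.column_stack([sw["temp_C"], sw["salinity"], sw["density"]])
        )
    prepared = prepare_reference(reference, seawater_model, CONSTANTS)
    obs = CalibrationObservations.from_tables(prepared, assay)
    fit = bootstrap_calibration(obs, CONSTANTS, n_reps=config.n_bootstrap, seed=config.seed)
    calibrated = calibrate_assay_table(assay, fit)
    write_table(calibrated, out / "assay_calibrated.csv")
    result = {
        "status": "ok",
        "S": fit.S,
        "S_se": fit.S_se,
        "p_p_hat": fit.p_p_hat,
        "p_p_hat_se": fit.p_p_hat_se,
        "fold_correlation": fit.fold_correlation,
        "n_reps": fit.n_reps,
        "n_reference_used": int((1 - obs.is_study).sum()),
        "n_excluded": sum(r.excluded for r in prepared),
    }
    if seawater_model is not None:
        result["seawater_max_residual"] = seawater_model.fit_residual_max
    (out / "calibration.json").write_text(json.dumps(result, indent=2))
    return result


def _run_fitness(config: PipelineConfig, out: Path) -> dict:
    df = read_table(config.competition_table, "s4")
    results = {}
    regimes = [r for r in df["sel_cond"].unique() if r != "init"]
    genotypes = [g for g in df["geno"].unique() if g not in ("AN", "alone")]
    for geno in genotypes:
        for regime in regimes:
            try:
                series = competition_series_from_table(df, geno, regime)
            except ConfigError:
                continue
            est = selection_coefficient(series, n_resamples=config.n_resamples, seed=config.seed)
            results[f"{geno}:{regime}"] = {
                "coefficient": est.coefficient,
                "standard_error": est.standard_error,
                "ci95": list(est.ci95),
                "p_value": est.p_value,
            }
    if not results:
        raise ConfigError("no competition series to estimate in the table")
    (out / "fitness.json").write_text(json.dumps(results, indent=2))
    return {"status": "ok", **results}


def _run_doubling(config: PipelineConfig, out: Path) -> dict:
    df = read_table(config.nuclei_table, "nuclei")
    series = nuclei_series_from_table(df)
    est = nuclear_doubling_time(series)
    result = {
        "status": "ok",
        "doubling_time_h": est.doubling_time,
        "slope": est.slope,
        "r_squared": est.r_squared,
        "low_confidence": est.low_confidence,
    }
    (out / "doubling.json").write_text(json.dumps(result, indent=2))
    return result


def _run_heritability(config: PipelineConfig, out: Path) -> dict:
    df = read_table(config.phenotype_table, "phenotypes")
    res = partition_variance(df, log_phenotypes=config.log_phenotypes)
    result = {
        "status": "ok",
        "H": res.H,
        "f_statistic": res.f_statistic,
        "df_between": res.df_between,
        "df_within": res.df_within,
        "per_phenotype": {
            name: {"H": r.H, "f_statistic": r.f_statistic}
            for name, r in (res.per_phenotype or {}).items()
        },
    }
    (out / "heritability.json").write_text(json.dumps(result, indent=2))
    return result


_STAGE_RUNNERS = {
    "calibrate": _run_calibrate,
    "fitness": _run_fitness,
    "doubling": _run_doubling,
    "heritability": _run_heritability,
}
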