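"""Readers/writers for the study table schemas, with validation.

Canonical interchange is UTF-8 CSV with "." decimals; tab-separated files are
auto-detected and spreadsheet exports (.xlsx) are accepted.  Header names are
validated case-sensitively against the declared schema and row-level problems
are collected with line numbers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .physics import CONSTANTS

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "read_table", "write_table", "load_yaml_config"]

#: Mandatory columns per schema.  Extra columns pass through untouched.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "s1": ("V_au", "R_meters", "species", "genotype", "temp", "hours_growth"),
    "s2": ("classification", "salt_percent", "V_meters_per_second", "R_meters"),
    "s3": ("temp_C", "salinity", "density"),
    "s4": ("batch", "rep", "geno", "time", "sel_cond", "NOT_CLUMPY", "YES_CLUMPY"),
    "od": ("time_s", "od600"),
    "nuclei": ("time_h", "ploidy", "fraction"),
    "nuclei_cells": ("time_h", "nuclei", "perimeter_um"),
    "phenotypes": ("genotype", "temp", "hours", "phenotype", "value"),
}

_NUMERIC_COLUMNS: dict[str, tuple[str, ...]] = {
    "s1": ("V_au", "R_meters", "temp", "hours_growth"),
    "s2": ("salt_percent", "V_meters_per_second", "R_meters"),
    "s3": ("temp_C", "salinity", "density"),
    "s4": ("time", "NOT_CLUMPY", "YES_CLUMPY"),
    "od": ("time_s", "od600"),
    "nuclei": ("time_h", "ploidy", "fraction"),
    "nuclei_cells": ("time_h", "nuclei", "perimeter_um"),
    "phenotypes": ("temp", "hours", "value"),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a table against one of the named schemas.

    Raises :class:`SchemaError` listing any missing mandatory columns and
    :class:`InputError` (with row numbers) when cells fail validation.
    """
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}", missing=missing)

    errors: list[str] = []
    for col in _NUMERIC_COLUMNS.get(schema, ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            errors.append(f"row {i + 2}: unparseable {col}={df.at[i, col]!r}")
        df[col] = coerced

    if schema == "s4":
        neg = df.index[(df["NOT_CLUMPY"] < 0) | (df["YES_CLUMPY"] < 0)]
        for i in neg:
            errors.append(f"row {i + 2}: negative count")
        if "N" in df.columns:
            n = pd.to_numeric(df["N"], errors="coerce")
            over = df.index[df["YES_CLUMPY"] > n.fillna(np.inf)]
            for i in over:
                errors.append(f"row {i + 2}: YES_CLUMPY exceeds total N")
    elif schema == "s1":
        bad = df.index[(df["V_au"] <= 0) | (df["R_meters"] <= 0)]
        for i in bad:
            errors.append(f"row {i + 2}: non-positive V_au or R_meters")
    elif schema == "s2":
        bad = df.index[(df["R_meters"] <= 0) | (df["V_meters_per_second"] <= 0)]
        for i in bad:
            errors.append(f"row {i + 2}: non-positive radius or velocity")
        _check_precomputed_density(df, path.name)
    elif schema == "nuclei":
        bad = df.index[(df["ploidy"] < 1) | (df["fraction"] < 0) | (df["fraction"] > 1)]
        for i in bad:
            errors.append(f"row {i + 2}: invalid ploidy or fraction")

    if errors:
        raise InputError(f"{path.name}: {len(errors)} invalid rows: " + "; ".join(errors[:10]))
    return df


def _check_precomputed_density(df: pd.DataFrame, name: str, tol: float = 1.0) -> None:
    """Recompute Pp_ from Pf/V/R where present; log mismatches beyond ``tol`` kg/m^3."""
    if not {"Pf", "Pp_"}.issubset(df.columns):
        return
    pf = pd.to_numeric(df["Pf"], errors="coerce")
    recomputed = pf + df["V_meters_per_second"] / (CONSTANTS.stokes_prefactor * df["R_meters"] ** 2)
    diff = (pd.to_numeric(df["Pp_"], errors="coerce") - recomputed).abs()
    bad = diff.index[diff > tol]
    for i in bad:
        logger.warning(
            "%s row %d: precomputed Pp_ deviates from Stokes inversion by %.3g kg/m^3",
            name, i + 2, diff[i],
        )


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as UTF-8 CSV preserving column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_yaml_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} must be a mapping")
    return cfg
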