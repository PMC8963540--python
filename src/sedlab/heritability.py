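"""Broad-sense heritability via fixed-effects variance partitioning.

Phenotypic variance is split into the part explained by genotype x environment
group means and a residual; heritability is the explained fraction,
H = SS_between / SS_total = 1 - SS_within / SS_total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["HeritabilityResult", "partition_variance", "DEFAULT_GROUPING"]

DEFAULT_GROUPING = ("genotype", "temp", "hours")


@dataclass(frozen=True)
class HeritabilityResult:
    """One-way variance decomposition on group means."""

    H: float | None
    f_statistic: float | None
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    n_groups: int
    n_obs: int
    message: str | None = None
    per_phenotype: dict | None = None


def _one_way(values: np.ndarray, groups: np.ndarray) -> HeritabilityResult:
    n = values.size
    uniq, inverse = np.unique(groups, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise InputError("variance partition needs at least 2 groups")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    group_means = np.bincount(inverse, weights=values) / np.bincount(inverse)
    fitted = group_means[inverse]
    ss_within = float(np.sum((values - fitted) ** 2))
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    if ss_total <= 0:
        return HeritabilityResult(
            H=None, f_statistic=None, df_between=df_b, df_within=df_w,
            ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
            n_groups=k, n_obs=n, message="zero total variance; H undefined",
        )
    h = ss_between / ss_total
    f = (ss_between / df_b) / (ss_within / df_w) if df_w > 0 and ss_within > 0 else np.inf
    return HeritabilityResult(
        H=float(h), f_statistic=float(f), df_between=df_b, df_within=df_w,
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        n_groups=k, n_obs=n,
    )


def partition_variance(
    table: pd.DataFrame,
    grouping: tuple[str, ...] = DEFAULT_GROUPING,
    value_col: str = "value",
    phenotype_col: str = "phenotype",
    log_phenotypes: tuple[str, ...] = (),
) -> HeritabilityResult:
    """Partition phenotypic variance over genotype x environment groups.

    When several phenotypes are present, each is partitioned separately (the
    ``per_phenotype`` dict) and the headline result pools all data with the
    phenotype as an extra grouping factor.  Phenotypes named in
    ``log_phenotypes`` are natural-log transformed first (e.g. sedimentation
    rates, whose error is multiplicative).
    """
    missing = [c for c in (*grouping, value_col) if c not in table.columns]
    if missing:
        raise InputError(f"table is missing columns: {missing}")
    df = table.copy()
    values = df[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("phenotype values must be finite")

    has_pheno = phenotype_col in df.columns
    if log_phenotypes:
        if not has_pheno:
            raise InputError(f"log_phenotypes given but no {phenotype_col!r} column present")
        mask = df[phenotype_col].isin(log_phenotypes).to_numpy()
        if np.any(values[mask] <= 0):
            raise InputError("log transform requested for non-positive values")
        values = values.copy()
        values[mask] = np.log(values[mask])

    group_cols = [*grouping, phenotype_col] if has_pheno else list(grouping)
    labels = df[group_cols].astype(str).agg("|".join, axis=1).to_numpy()
    pooled = _one_way(values, labels)

    per_pheno = None
    if has_pheno and df[phenotype_col].nunique() > 1:
        per_pheno = {}
        plain_labels = df[list(grouping)].astype(str).agg("|".join, axis=1).to_numpy()
        for name in df[phenotype_col].unique():
            sel = (df[phenotype_col] == name).to_numpy()
            try:
                per_pheno[name] = _one_way(values[sel], plain_labels[sel])
            except InputError:
                continue
    return HeritabilityResult(
        H=pooled.H,
        f_statistic=pooled.f_statistic,
        df_between=pooled.df_between,
        df_within=pooled.df_within,
        ss_between=pooled.ss_between,
        ss_within=pooled.ss_within,
        ss_total=pooled.ss_total,
        n_groups=pooled.n_groups,
        n_obs=pooled.n_obs,
        message=pooled.message,
        per_phenotype=per_pheno,
    )
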