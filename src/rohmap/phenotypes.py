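"""Production-trait phenotypes and fixed-effect adjustment.

The phenotype table carries one record per animal: farm, year and sex as
fixed-effect factors, weight before fattening (kg) and fattening days as
covariates, and the production traits — net meat weight (NMW), carcass
weight (CW) and live weight (LW) in kg, plus average daily gain
(ADG, kg/day) derived as weight gain over the fattening period divided by
fattening days.

Adjustment fits an ordinary least-squares model of a trait on the factors
(reference-level coding) and covariates and returns the residuals as the
adjusted phenotype.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

FACTORS = ("farm", "year", "sex")
COVARIATES = ("weight_before_fattening", "fattening_days")
TRAITS = ("NMW", "CW", "ADG", "LW")

REQUIRED_COLUMNS = ("sample",) + FACTORS + COVARIATES


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV; derives ADG from end weight when absent."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if "ADG" not in df.columns and "end_weight" in df.columns:
        df["ADG"] = compute_adg(df["end_weight"] - df["weight_before_fattening"],
                                df["fattening_days"])
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def compute_adg(weight_gain_kg, fattening_days):
    """Average daily gain: body-weight gain divided by fattening days."""
    gain = np.asarray(weight_gain_kg, dtype=float)
    days = np.asarray(fattening_days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("fattening_days must be positive")
    if np.any(gain < 0):
        warnings.warn("negative weight gain: ADG will be negative", stacklevel=2)
    out = gain / days
    return float(out) if out.ndim == 0 else out


def design_matrix(table: pd.DataFrame,
                  factors: Sequence[str] = FACTORS,
                  covariates: Sequence[str] = COVARIATES) -> pd.DataFrame:
    """Full-rank design: intercept, reference-coded factor dummies
    (reference = first level in sort order), covariates."""
    parts = [pd.Series(1.0, index=table.index, name="intercept")]
    for f in factors:
        levels = sorted(table[f].astype(str).unique())
        for lev in levels[1:]:
            parts.append((table[f].astype(str) == lev).astype(float)
                         .rename(f"{f}[{lev}]"))
    for c in covariates:
        parts.append(table[c].astype(float).rename(c))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for col in X.columns[1:]:
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def adjust_phenotype(table: pd.DataFrame, trait: str,
                     factors: Sequence[str] = FACTORS,
                     covariates: Sequence[str] = COVARIATES) -> pd.Series:
    """OLS residuals of ``trait`` on the fixed-effect design.

    Rows with a missing trait or design value are dropped (count logged);
    the result is a Series of residuals indexed by sample id.
    """
    cols = [trait, *factors, *covariates]
    sub = table.dropna(subset=[c for c in cols if c in table.columns])
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.info("adjust_phenotype(%s): dropped %d rows with missing values",
                    trait, n_dropped)
    X = design_matrix(sub, factors, covariates)
    if len(sub) <= X.shape[1]:
        raise ValueError(f"n={len(sub)} too small for {X.shape[1]} design columns")
    fit = sm.OLS(sub[trait].astype(float).to_numpy(), X.to_numpy()).fit()
    logger.debug("adjust_phenotype(%s): R2=%.4f", trait, fit.rsquared)
    return pd.Series(fit.resid, index=sub["sample"].to_numpy(), name=trait)
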