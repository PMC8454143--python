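"""Genomic relationship matrix and REML mixed-model validation.

The validating model for a candidate ROH region is

    y = Xb + u + e,   u ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

with y the raw trait, X the fixed effects (intercept, farm, year, sex,
weight before fattening, fattening days, and the region's carrier
indicator) and G the VanRaden method-1 genomic relationship matrix:
centred allele-B dosages W = M - 2p scaled as G = W W' / (2 sum p(1-p)),
allele frequencies estimated from the sample.

REML maximises the restricted likelihood over the variance ratio
lambda = sigma_g^2 / sigma_e^2 on the eigenbasis of G, which reduces each
likelihood evaluation to diagonal weighting; the optimum is found by
bounded scalar minimisation on log10(lambda).  The ROH coefficient is
tested with a Wald z statistic at the REML variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix

_LOG_LAMBDA_BOUNDS = (-8.0, 8.0)


@dataclass
class GRM:
    """Additive genomic relationship matrix over ordered sample ids."""

    sample_ids: list
    matrix: np.ndarray
    n_snps: int
    freq_source: str = "sample"

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape inconsistent with sample ids")

    def align(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.sample_ids.index(i) for i in ids]
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class MixedModelResult:
    """REML fit with a Wald test on the ROH-presence coefficient."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    sigma_g2: float
    sigma_e2: float
    loglik: float
    roh_effect: float
    roh_se: float
    wald_z: float
    wald_p: float
    boundary: bool = False
    degenerate: bool = False
    log: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.wald_p < 0.05


def build_grm(g: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from a QC'd matrix.

    Missing genotypes are mean-imputed per SNP for this step only;
    monomorphic SNPs are excluded with a warning.
    """
    calls = g.calls.astype(float)
    miss = g.calls == MISSING
    calls[miss] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        import warnings
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from GRM",
                      stacklevel=2)
    calls = calls[:, poly]
    p = p[poly]
    inds = np.where(np.isnan(calls))
    calls[inds] = (2 * p)[inds[1]]
    w = calls - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs: cannot build GRM")
    mat = (w @ w.T) / denom
    return GRM(sample_ids=list(g.samples), matrix=mat, n_snps=int(poly.sum()))


def _reml_profile(log10_lam: float, d: np.ndarray, yt: np.ndarray,
                  xt: np.ndarray):
    """Profile restricted log-likelihood at a given log10 variance ratio.

    Returns (loglik, sigma_e2, beta, xtwx_inv)."""
    lam = 10.0 ** log10_lam
    v = lam * d + 1.0            # eigenvalues of (lam G + I)
    w = 1.0 / v
    xtw = xt * w[:, None]
    xtwx = xt.T @ xtw
    xtwy = xtw.T @ yt
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ xtwy
    resid = yt - xt @ beta
    n, p = xt.shape
    rss = float(resid @ (w * resid))
    sigma_e2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * ((n - p) * np.log(sigma_e2) + np.log(v).sum()
                 + logdet_xtwx + (n - p))
    return ll, sigma_e2, beta, xtwx_inv


def reml_fit(y: np.ndarray, X: np.ndarray, grm: GRM | np.ndarray,
             eig=None):
    """REML variance components for a single-random-effect model.

    Returns a dict with sigma_g2, sigma_e2, loglik, lambda, beta, beta_cov,
    boundary and degenerate flags.  ``eig`` may carry a precomputed
    eigendecomposition (d, U) of G to amortise repeated fits.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValueError("y and X row counts differ")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is rank-deficient")
    if n <= p + 1:
        raise ValueError("not enough residual degrees of freedom")
    G = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    if eig is None:
        d, U = np.linalg.eigh(G)
        d = np.clip(d, 0.0, None)
    else:
        d, U = eig
    yt = U.T @ y
    xt = U.T @ X

    degenerate = float(d.max() - d.min()) <= 1e-10 * max(1.0, float(d.max()))
    if degenerate:
        # G proportional to I: sigma_g2 and sigma_e2 are not separable
        ll, sigma_e2, beta, xtwx_inv = _reml_profile(_LOG_LAMBDA_BOUNDS[0], d, yt, xt)
        return {"sigma_g2": 0.0, "sigma_e2": sigma_e2, "loglik": ll,
                "lambda": 0.0, "beta": beta,
                "beta_cov": sigma_e2 * xtwx_inv, "boundary": True,
                "degenerate": True, "eig": (d, U)}

    res = optimize.minimize_scalar(
        lambda t: -_reml_profile(t, d, yt, xt)[0],
        bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-9})
    if not res.success:
        raise RuntimeError(f"REML optimisation failed: {res}")
    t_hat = float(res.x)
    # compare against the lower boundary (sigma_g2 -> 0)
    ll_hat = _reml_profile(t_hat, d, yt, xt)[0]
    ll_lo = _reml_profile(_LOG_LAMBDA_BOUNDS[0], d, yt, xt)[0]
    boundary = False
    if ll_lo >= ll_hat - 1e-10:
        t_hat, boundary = _LOG_LAMBDA_BOUNDS[0], True
    elif t_hat >= _LOG_LAMBDA_BOUNDS[1] - 1e-6:
        boundary = True
    ll, sigma_e2, beta, xtwx_inv = _reml_profile(t_hat, d, yt, xt)
    lam = 10.0 ** t_hat if not (boundary and t_hat == _LOG_LAMBDA_BOUNDS[0]) else 0.0
    return {"sigma_g2": lam * sigma_e2, "sigma_e2": sigma_e2, "loglik": ll,
            "lambda": lam, "beta": beta, "beta_cov": sigma_e2 * xtwx_inv,
            "boundary": boundary, "degenerate": False, "eig": (d, U)}


def roh_association_test(trait_raw: pd.Series, design: pd.DataFrame,
                         roh_indicator: pd.Series, grm: GRM,
                         eig=None) -> MixedModelResult:
    """Wald test of an ROH-presence indicator in the REML mixed model.

    ``design`` is the fixed-effect design (including intercept) indexed by
    sample id; ``roh_indicator`` is 0/1 carrier status; all three inputs
    and the GRM are aligned on the design's sample order.
    """
    ids = list(design.index)
    ind = roh_indicator.loc[ids].to_numpy(dtype=float)
    if np.all(ind == ind[0]):
        raise ValueError("no carrier contrast: ROH indicator is constant")
    X = np.column_stack([design.to_numpy(dtype=float), ind])
    names = list(design.columns) + ["roh"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design rank-deficient after adding the ROH "
                         "indicator (separation with a factor level?)")
    y = trait_raw.loc[ids].to_numpy(dtype=float)
    G = grm.align(ids) if list(grm.sample_ids) != ids else grm.matrix
    fit = reml_fit(y, X, GRM(sample_ids=ids, matrix=G, n_snps=grm.n_snps),
                   eig=eig)
    se = np.sqrt(np.diag(fit["beta_cov"]))
    z = fit["beta"][-1] / se[-1]
    p = 2.0 * sps.norm.sf(abs(z))
    return MixedModelResult(
        beta=fit["beta"], se=se, names=names,
        sigma_g2=fit["sigma_g2"], sigma_e2=fit["sigma_e2"],
        loglik=fit["loglik"], roh_effect=float(fit["beta"][-1]),
        roh_se=float(se[-1]), wald_z=float(z), wald_p=float(p),
        boundary=fit["boundary"], degenerate=fit["degenerate"],
        log={"lambda": fit["lambda"]})


def compare_carriers(adjusted_trait: pd.Series, carrier: pd.Series):
    """Adjusted-trait distribution of carriers vs non-carriers.

    Returns (summary DataFrame, two-sided Wilcoxon p).  Each class needs
    at least two members.
    """
    common = adjusted_trait.index.intersection(carrier.index)
    vals = adjusted_trait.loc[common].to_numpy(dtype=float)
    is_carrier = carrier.loc[common].astype(bool).to_numpy()
    groups = {"carrier": vals[is_carrier], "non_carrier": vals[~is_carrier]}
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"{name} class has fewer than 2 members")
    rows = []
    for name, v in groups.items():
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": name, "n": int(v.size), "mean": float(v.mean()),
                     "q1": float(q1), "median": float(q2), "q3": float(q3)})
    from .association import wilcoxon_ranksum
    p = wilcoxon_ranksum(groups["carrier"], groups["non_carrier"])
    return pd.DataFrame(rows), p
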