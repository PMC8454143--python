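"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated by the
standard EM algorithm: every genotype pair except the double heterozygote
has unambiguous phase; the double heterozygote's coupling/repulsion split
is re-estimated each iteration from the current frequencies.  From the
converged frequencies, D = f(AB) - p(A) p(B), r^2 = D^2 / (pA pa pB pb)
and D' = D / Dmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class LDMatrix:
    variant_ids: list
    r2: np.ndarray
    dprime_abs: np.ndarray
    dprime_signed: np.ndarray

    def to_frame(self, which: str = "r2") -> pd.DataFrame:
        mat = {"r2": self.r2, "dprime": self.dprime_abs,
               "dprime_signed": self.dprime_signed}[which]
        return pd.DataFrame(mat, index=self.variant_ids, columns=self.variant_ids)


def _pair_loglik(f: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under
    haplotype frequencies f = [AB, Ab, aB, ab] with random mating."""
    hap = {(0, 0): f[0], (0, 1): f[1], (1, 0): f[2], (1, 1): f[3]}
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if table[i, j] == 0:
                continue
            prob = 0.0
            for a1 in (0, 1):
                for b1 in (0, 1):
                    a2, b2 = i - a1, j - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        prob += hap[(a1, b1)] * hap[(a2, b2)]
            ll += table[i, j] * np.log(max(prob, 1e-300))
    return float(ll)


def em_haplotype_freqs(geno1, geno2, tol: float = 1e-10,
                       max_iter: int = 1000,
                       return_trace: bool = False) -> np.ndarray:
    """EM haplotype frequencies [f_AB, f_Ab, f_aB, f_ab] for two loci.

    Dosages count the 'b' allele at each locus (A = dose 0 allele).
    Pairs with a missing call at either locus are dropped; both loci must
    remain polymorphic.
    """
    g1 = np.asarray(geno1)
    g2 = np.asarray(geno2)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    if g1.size == 0:
        raise ValueError("no complete genotype pairs")
    for g, name in ((g1, "locus 1"), (g2, "locus 2")):
        if np.all(g == g[0]):
            raise ValueError(f"{name} is monomorphic")
    # 3x3 genotype table, rows = locus1 dosage, cols = locus2 dosage
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (g1, g2), 1.0)
    n_hap = 2.0 * g1.size
    # fixed (phase-known) haplotype counts; indices 0=AB 1=Ab 2=aB 3=ab
    fixed = np.zeros(4)
    fixed[0] = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    fixed[1] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    fixed[2] = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    fixed[3] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    dh = table[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    f = np.full(4, 0.25)
    trace = []
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0 else coupling / denom
        counts = fixed.copy()
        counts[0] += dh * w
        counts[3] += dh * w
        counts[1] += dh * (1 - w)
        counts[2] += dh * (1 - w)
        f_new = counts / n_hap
        if return_trace:
            trace.append(_pair_loglik(f_new, table))
        converged = np.abs(f_new - f).max() < tol
        f = f_new
        if converged:
            break
    if return_trace:
        return f, trace
    return f


def ld_pair(geno1, geno2) -> Tuple[float, float, float]:
    """(r2, |D'|, signed D') for one locus pair."""
    f = em_haplotype_freqs(geno1, geno2)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    d = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom <= 0 else d * d / denom
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif d < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0
    dprime = 0.0 if dmax == 0 else d / dmax
    return float(min(r2, 1.0)), float(min(abs(dprime), 1.0)), float(dprime)


def ld_matrix(g: GenotypeMatrix, chrom: int,
              start_bp: Optional[int] = None,
              end_bp: Optional[int] = None) -> LDMatrix:
    """Pairwise LD for the SNPs of one chromosome region."""
    mask = (g.variants["chrom"] == chrom).to_numpy()
    if start_bp is not None:
        mask &= (g.variants["pos"] >= start_bp).to_numpy()
    if end_bp is not None:
        mask &= (g.variants["pos"] <= end_bp).to_numpy()
    idx = np.flatnonzero(mask)
    # keep polymorphic SNPs with at least one complete pair
    usable = []
    for vi in idx:
        col = g.calls[:, vi]
        obs = col[col != MISSING]
        if obs.size and not np.all(obs == obs[0]):
            usable.append(vi)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable (polymorphic) SNPs in region")
    k = len(usable)
    r2 = np.eye(k)
    dpa = np.eye(k)
    dps = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b, s = ld_pair(g.calls[:, usable[i]], g.calls[:, usable[j]])
            r2[i, j] = r2[j, i] = a
            dpa[i, j] = dpa[j, i] = b
            dps[i, j] = dps[j, i] = s
    ids = g.variants["id"].iloc[usable].tolist()
    return LDMatrix(variant_ids=ids, r2=r2, dprime_abs=dpa, dprime_signed=dps)


def ld_heatmap(ld: LDMatrix, path, which: str = "r2") -> None:
    """Plain raster heatmap of the LD matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    mat = {"r2": ld.r2, "dprime": ld.dprime_abs}[which]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="Reds")
    ax.set_title({"r2": r"$r^2$", "dprime": r"$|D'|$"}[which])
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
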