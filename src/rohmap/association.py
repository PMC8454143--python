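"""Extreme-group association between consensus ROH and production traits.

The design follows homozygosity-mapping practice: rank animals by an
adjusted trait, take the top-n and bottom-n as high/low groups (n = 300 at
full scale), compare total ROH burden between groups with a Wilcoxon
rank-sum test, and test each consensus region's carrier proportion
between groups with a two-sided Fisher's exact test on the 2x2 table
(high/low x carrier/non-carrier).  No multiplicity correction is applied
by default; Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .consensus import ConsensusROH
from .scanner import ROHSegment
from .stats import IndividualROHSummary


@dataclass(frozen=True)
class ExtremeGroups:
    trait: str
    high_ids: tuple
    low_ids: tuple

    @property
    def n(self) -> int:
        return len(self.high_ids)


@dataclass(frozen=True)
class RegionAssociation:
    """Fisher 2x2 result for one consensus region and trait."""

    region: ConsensusROH
    trait: str
    a: int  # high, carrier
    b: int  # high, non-carrier
    c: int  # low, carrier
    d: int  # low, non-carrier
    odds_ratio: float
    fisher_p: float
    significant: bool
    testable: bool = True


def pearson_roh_trait(summaries: Iterable[IndividualROHSummary],
                      adjusted: pd.Series, trait: str,
                      length_class: Optional[str] = None):
    """Pearson r / p between per-individual total ROH length (optionally one
    size class) and the adjusted trait, over samples present in both."""
    if length_class is None:
        lengths = {s.sample_id: s.total_length_bp for s in summaries}
    else:
        lengths = {s.sample_id: s.length_by_class[length_class] for s in summaries}
    common = [sid for sid in adjusted.index if sid in lengths]
    if len(common) < 3:
        raise ValueError("need at least 3 matched samples")
    x = np.array([lengths[sid] for sid in common], dtype=float)
    y = adjusted.loc[common].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def split_extremes(adjusted: pd.Series, trait: str, n: int = 300) -> ExtremeGroups:
    """Top-n / bottom-n split by adjusted trait; ties broken by sample id."""
    if 2 * n > len(adjusted):
        raise ValueError(f"2n={2 * n} exceeds population size {len(adjusted)}")
    order = sorted(adjusted.items(), key=lambda kv: (-kv[1], kv[0]))
    if adjusted.nunique() == 1:
        warnings.warn("all trait values tied: extreme groups determined by id",
                      stacklevel=2)
    high = tuple(sid for sid, _ in order[:n])
    low = tuple(sid for sid, _ in sorted(order[-n:], key=lambda kv: (kv[1], kv[0])))
    return ExtremeGroups(trait=trait, high_ids=high, low_ids=low)


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for min(n, m) <= 10 without
    ties, else normal approximation with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio; Haldane 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_test_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditions on both margins and sums the hypergeometric probabilities
    of all tables no more probable than the observed one (the same
    convention as R's fisher.test / scipy's two-sided mode).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return 1.0
    x = np.arange(lo, hi + 1)
    logw = (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    obs = w[a - lo]
    return float(min(1.0, w[w <= obs * (1 + 1e-7)].sum()))


def fisher_enrichment(consensus_list: Sequence[ConsensusROH],
                      carriers: Dict[str, set] | pd.DataFrame,
                      groups: ExtremeGroups,
                      alpha: float = 0.05,
                      bh_correct: bool = False) -> List[RegionAssociation]:
    """Per-region 2x2 Fisher tests of carrier proportion, high vs low group.

    ``carriers`` maps region name -> set of carrier sample ids (or a
    samples x regions boolean DataFrame).  Regions with zero carriers in
    both groups are returned untestable with p = 1.
    """
    if isinstance(carriers, pd.DataFrame):
        carriers = {col: set(carriers.index[carriers[col]]) for col in carriers}
    high, low = set(groups.high_ids), set(groups.low_ids)
    results: List[RegionAssociation] = []
    pvals = []
    for region in consensus_list:
        cset = carriers[region.name]
        a = len(high & cset)
        b = len(high) - a
        c = len(low & cset)
        d = len(low) - c
        testable = (a + c) > 0
        p = fisher_test_2x2(a, b, c, d) if testable else 1.0
        results.append(RegionAssociation(
            region=region, trait=groups.trait, a=a, b=b, c=c, d=d,
            odds_ratio=odds_ratio_2x2(a, b, c, d), fisher_p=p,
            significant=False, testable=testable))
        pvals.append(p)
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        flags = list(reject)
    else:
        flags = [p < alpha for p in pvals]
    return [RegionAssociation(**{**r.__dict__, "significant": bool(f) and r.testable})
            for r, f in zip(results, flags)]


def associations_to_frame(results: Iterable[RegionAssociation]) -> pd.DataFrame:
    rows = [{"region": r.region.name, "chrom": r.region.chrom,
             "start_bp": r.region.start_bp, "end_bp": r.region.end_bp,
             "trait": r.trait, "high_carrier": r.a, "high_noncarrier": r.b,
             "low_carrier": r.c, "low_noncarrier": r.d,
             "odds_ratio": r.odds_ratio, "fisher_p": r.fisher_p,
             "significant": r.significant, "testable": r.testable}
            for r in results]
    return pd.DataFrame(rows)


def total_roh_by_group(summaries: Iterable[IndividualROHSummary],
                       groups: ExtremeGroups):
    """(high totals, low totals) of per-individual ROH length in bp."""
    totals = {s.sample_id: s.total_length_bp for s in summaries}
    x = np.array([totals.get(sid, 0) for sid in groups.high_ids], dtype=float)
    y = np.array([totals.get(sid, 0) for sid in groups.low_ids], dtype=float)
    return x, y
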