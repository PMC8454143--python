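"""Independent brute-force reference implementations used as oracles.

Everything here is written with plain Python loops and first-principles
enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

MISSING = -1


# ---------------------------------------------------------------------------
# sliding-window ROH detection (criteria i-vi), loop-based
# ---------------------------------------------------------------------------

def brute_window_rates(calls, window_snps=50, window_max_het=1,
                       window_max_missing=5):
    """Per-SNP hit rate by explicit enumeration of every window."""
    m = len(calls)
    if m < window_snps:
        return [0.0] * m
    ok = []
    for w in range(m - window_snps + 1):
        chunk = calls[w:w + window_snps]
        n_het = sum(1 for x in chunk if x == 1)
        n_mis = sum(1 for x in chunk if x == MISSING)
        ok.append(n_het <= window_max_het and n_mis <= window_max_missing)
    rates = []
    for i in range(m):
        wins = [w for w in range(len(ok)) if w <= i <= w + window_snps - 1]
        rates.append(sum(ok[w] for w in wins) / len(wins))
    return rates


def brute_roh(calls, positions, window_snps=50, window_max_het=1,
              window_max_missing=5, window_hit_threshold=0.05,
              min_length_bp=500_000, min_snps=100,
              min_density_bp_per_snp=50_000, max_gap_bp=100_000,
              roh_max_het=1, roh_max_missing=2):
    """ROH for one sample on one chromosome, per the documented rule:

    candidate SNPs have window hit rate >= threshold; maximal candidate
    stretches are split at gaps > max_gap_bp; within each stretch, runs
    are emitted greedily left to right (grow until the het/missing budget
    would be exceeded, trim to homozygous endpoints), keeping runs that
    pass the length / SNP-count / density filters.
    """
    rates = brute_window_rates(calls, window_snps, window_max_het,
                               window_max_missing)
    m = len(calls)
    candidate = [r >= window_hit_threshold for r in rates]
    # maximal candidate stretches
    stretches = []
    i = 0
    while i < m:
        if candidate[i]:
            j = i
            while j + 1 < m and candidate[j + 1]:
                j += 1
            stretches.append((i, j))
            i = j + 1
        else:
            i += 1
    # split at big gaps
    pieces = []
    for a, b in stretches:
        start = a
        for k in range(a + 1, b + 1):
            if positions[k] - positions[k - 1] > max_gap_bp:
                pieces.append((start, k - 1))
                start = k
        pieces.append((start, b))

    out = []
    for a, b in pieces:
        s = a
        while s <= b:
            while s <= b and calls[s] not in (0, 2):
                s += 1
            if s > b:
                break
            n_het = n_mis = 0
            e = s
            violator = None
            for j in range(s, b + 1):
                h = 1 if calls[j] == 1 else 0
                mm = 1 if calls[j] == MISSING else 0
                if n_het + h > roh_max_het or n_mis + mm > roh_max_missing:
                    violator = j
                    break
                n_het += h
                n_mis += mm
                e = j
            while e > s and calls[e] not in (0, 2):
                if calls[e] == 1:
                    n_het -= 1
                else:
                    n_mis -= 1
                e -= 1
            n = e - s + 1
            length = positions[e] - positions[s] + 1
            if (calls[s] in (0, 2) and calls[e] in (0, 2)
                    and length >= min_length_bp and n >= min_snps
                    and length / n <= min_density_bp_per_snp):
                out.append((positions[s], positions[e], n, n_het, n_mis))
            s = (b + 1) if violator is None else violator + 1
    return out


# ---------------------------------------------------------------------------
# exact tests by enumeration
# ---------------------------------------------------------------------------

def hwe_exact_enumeration(n_hom_a, n_het, n_hom_b):
    """Exact HWE p by enumerating genotype configurations with the observed
    allele counts, exact rational arithmetic."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    configs = {}
    for het in range(min(n_a, n_b) + 1):
        if (n_a - het) % 2:
            continue
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        if hom_a < 0 or hom_b < 0:
            continue
        weight = Fraction(math.factorial(n), math.factorial(hom_a)
                          * math.factorial(het) * math.factorial(hom_b)) * 2 ** het
        configs[het] = weight
    total = sum(configs.values())
    probs = {het: Fraction(w, total) for het, w in configs.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher p by enumerating tables with fixed margins.

    Works in exact integer weights (unnormalised hypergeometric masses),
    so the 'no more probable than observed' comparison is tie-exact.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    total = sum(weights)
    if total == 0:
        return 1.0
    obs = weights[a - lo]
    return float(Fraction(sum(w for w in weights if w <= obs), total))


def wilcoxon_exact_enumeration(x, y):
    """Two-sided rank-sum p by enumerating all group assignments of the
    pooled ranks (no ties)."""
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    mean = nx * (nx + ny + 1) / 2
    sums = [sum(comb) for comb in
            itertools.combinations(range(1, nx + ny + 1), nx)]
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)


# ---------------------------------------------------------------------------
# two-locus LD with unambiguous phase
# ---------------------------------------------------------------------------

def counting_haplotype_freqs(g1, g2):
    """Haplotype frequencies by direct counting; only valid when no
    double-heterozygote pairs occur (phase unambiguous)."""
    counts = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
    n = 0
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        if a == 1 and b == 1:
            raise ValueError("double heterozygote: phase ambiguous")
        # alleles at locus1: a copies of '1'; locus2: b copies
        al1 = [1] * a + [0] * (2 - a)
        al2 = [1] * b + [0] * (2 - b)
        if a == 1:
            hap_pairs = [(al1[0], al2[0]), (al1[1], al2[1])]
        elif b == 1:
            hap_pairs = [(al1[0], al2[0]), (al1[1], al2[1])]
        else:
            hap_pairs = [(al1[0], al2[0]), (al1[1], al2[1])]
        for h in hap_pairs:
            counts[h] += 1
        n += 2
    return {k: v / n for k, v in counts.items()}


def counting_r2(g1, g2):
    f = counting_haplotype_freqs(g1, g2)
    p1 = f[(1, 0)] + f[(1, 1)]
    p2 = f[(0, 1)] + f[(1, 1)]
    d = f[(1, 1)] - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    return 0.0 if denom == 0 else d * d / denom
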