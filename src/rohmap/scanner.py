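"""Sliding-window ROH detection.

The detector reproduces the PLINK ``--homozyg`` two-stage screen:

1. *Window screen.*  A window of 50 consecutive SNPs is "homozygous" when
   it contains at most 1 heterozygote and at most 5 missing calls.  Each
   SNP's hit rate is the fraction of windows containing it that are
   homozygous; SNPs with hit rate >= 0.05 become ROH candidates.
2. *Segment criteria.*  Candidate SNP stretches are split at inter-SNP
   gaps above 100 kb and scanned left to right into maximal runs that hold
   at most 1 heterozygous and 2 missing calls, start and end on a
   homozygous non-missing SNP, and pass the final filters: length >=
   500 kb, >= 100 SNPs, average spacing <= 50 kb/SNP.

Segment length is ``end_bp - start_bp + 1`` (1-based inclusive, SNP
positions).  When a stretch holds more heterozygotes than one segment may
carry, runs are emitted greedily left to right (each run grows until the
het/missing budget would be exceeded, is trimmed back to a homozygous
endpoint, and scanning resumes after the violating SNP), so emitted
segments never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

SIZE_CLASSES = ("Small", "Medium", "Large")


@dataclass(frozen=True)
class ScannerParams:
    """Window and segment criteria for ROH detection (PLINK-style defaults)."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    min_length_bp: int = 500_000
    min_snps: int = 100
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 100_000
    roh_max_het: int = 1
    roh_max_missing: int = 2

    def __post_init__(self) -> None:
        for name in ("window_snps", "min_length_bp", "min_snps",
                     "min_density_bp_per_snp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity in one individual (1-based inclusive bp)."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int
    size_class: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlaps(self, start_bp: int, end_bp: int) -> bool:
        return self.start_bp <= end_bp and start_bp <= self.end_bp

    def covers(self, start_bp: int, end_bp: int) -> bool:
        return self.start_bp <= start_bp and self.end_bp >= end_bp


def classify_size(length_bp: int,
                  params: ScannerParams = ScannerParams()) -> str:
    """Assign the size class: Small [0.5, 1) Mb, Medium [1, 5] Mb, Large > 5 Mb."""
    if length_bp < params.min_length_bp:
        raise ValueError(f"length {length_bp} bp is below the minimum ROH "
                         f"length {params.min_length_bp} bp")
    if length_bp < 1_000_000:
        return "Small"
    if length_bp <= 5_000_000:
        return "Medium"
    return "Large"


def window_hit_rates(calls: np.ndarray,
                     params: ScannerParams = ScannerParams()) -> np.ndarray:
    """Per-SNP fraction of containing windows that are homozygous.

    ``calls`` is one sample's dosage vector on one chromosome, ordered by
    position.  Chromosomes shorter than one window yield all-zero rates
    (no candidate SNPs).
    """
    calls = np.asarray(calls)
    m = calls.size
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=float)
    het = (calls == 1).astype(np.int32)
    miss = (calls == MISSING).astype(np.int32)
    het_c = np.concatenate(([0], np.cumsum(het)))
    miss_c = np.concatenate(([0], np.cumsum(miss)))
    n_win = m - w + 1
    starts = np.arange(n_win)
    ok = ((het_c[starts + w] - het_c[starts] <= params.window_max_het)
          & (miss_c[starts + w] - miss_c[starts] <= params.window_max_missing))
    ok_c = np.concatenate(([0], np.cumsum(ok)))
    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    hits = ok_c[hi + 1] - ok_c[lo]
    return hits / (hi - lo + 1)


def _true_stretches(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def _emit_runs(calls: np.ndarray, pos: np.ndarray, lo: int, hi: int,
               params: ScannerParams):
    """Greedy left-to-right maximal qualifying runs inside candidate
    stretch [lo, hi) (gap constraint already satisfied)."""
    is_hom = (calls == 0) | (calls == 2)
    runs = []
    s = lo
    while s < hi:
        while s < hi and not is_hom[s]:
            s += 1
        if s >= hi:
            break
        n_het = n_miss = 0
        e = s
        violator = None
        for j in range(s, hi):
            h = int(calls[j] == 1)
            mm = int(calls[j] == MISSING)
            if n_het + h > params.roh_max_het or n_miss + mm > params.roh_max_missing:
                violator = j
                break
            n_het += h
            n_miss += mm
            e = j
        while e > s and not is_hom[e]:
            if calls[e] == 1:
                n_het -= 1
            else:
                n_miss -= 1
            e -= 1
        n_snps = e - s + 1
        length = int(pos[e]) - int(pos[s]) + 1
        if (is_hom[s] and is_hom[e]
                and length >= params.min_length_bp
                and n_snps >= params.min_snps
                and length / n_snps <= params.min_density_bp_per_snp):
            runs.append((s, e, n_het, n_miss))
        s = hi if violator is None else violator + 1
    return runs


def call_roh(calls: np.ndarray, variants: pd.DataFrame,
             params: ScannerParams = ScannerParams(),
             sample_id: str = "") -> List[ROHSegment]:
    """Detect ROH for one sample across all chromosomes in ``variants``."""
    calls = np.asarray(calls)
    if calls.shape != (len(variants),):
        raise ValueError(f"calls length {calls.shape} does not match "
                         f"{len(variants)} variants")
    chroms = variants["chrom"].to_numpy()
    positions = variants["pos"].to_numpy()
    segments: List[ROHSegment] = []
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        pos = positions[cmask]
        c = calls[cmask]
        rates = window_hit_rates(c, params)
        candidate = rates >= params.window_hit_threshold
        for lo, hi in _true_stretches(candidate):
            # split at inter-SNP gaps above max_gap_bp
            cut = np.flatnonzero(np.diff(pos[lo:hi]) > params.max_gap_bp) + lo + 1
            bounds = [lo, *cut.tolist(), hi]
            for a, b in zip(bounds[:-1], bounds[1:]):
                for s, e, n_het, n_miss in _emit_runs(c, pos, a, b, params):
                    length = int(pos[e]) - int(pos[s]) + 1
                    segments.append(ROHSegment(
                        sample_id=sample_id, chrom=int(chrom),
                        start_bp=int(pos[s]), end_bp=int(pos[e]),
                        n_snps=e - s + 1, n_het=n_het, n_missing=n_miss,
                        size_class=classify_size(length, params)))
    segments.sort(key=lambda r: (r.chrom, r.start_bp))
    return segments


def detect_roh_population(g: GenotypeMatrix,
                          params: ScannerParams = ScannerParams()
                          ) -> List[ROHSegment]:
    """ROH for every sample; ordered by (sample, chrom, start)."""
    segments: List[ROHSegment] = []
    for si, sid in enumerate(g.samples):
        segments.extend(call_roh(g.calls[si], g.variants, params, sample_id=sid))
    return segments


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments in a PLINK .hom-like layout (kb column included)."""
    rows = [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.length_bp / 1000.0,
             s.n_snps, s.n_het, s.n_missing, s.size_class) for s in segments]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp",
                                       "kb", "n_snps", "n_het", "n_missing",
                                       "class"])


def frame_to_segments(df: pd.DataFrame) -> List[ROHSegment]:
    return [ROHSegment(sample_id=str(r["sample"]), chrom=int(r["chrom"]),
                       start_bp=int(r["start_bp"]), end_bp=int(r["end_bp"]),
                       n_snps=int(r["n_snps"]), n_het=int(r["n_het"]),
                       n_missing=int(r["n_missing"]), size_class=str(r["class"]))
            for r in df.to_dict("records")]
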