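"""Per-individual, per-chromosome and per-size-class ROH summaries.

FROH — the genomic inbreeding coefficient — is the fraction of the
SNP-covered autosomal genome (first to last SNP per chromosome) lying
inside an individual's ROH.  Using the SNP-covered span rather than the
assembly length keeps the coefficient self-contained and independent of
un-genotyped chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeMatrix
from .scanner import SIZE_CLASSES, ROHSegment


@dataclass(frozen=True)
class IndividualROHSummary:
    sample_id: str
    n_roh: int
    total_length_bp: int
    length_by_class: dict  # Small/Medium/Large -> bp
    count_by_class: dict
    froh: float


def covered_autosome_length(g: GenotypeMatrix) -> int:
    """Sum over chromosomes of (last SNP bp - first SNP bp + 1)."""
    total = 0
    for chrom in g.chromosomes():
        pos = g.variant_positions(chrom)
        if pos.size:
            total += int(pos[-1]) - int(pos[0]) + 1
    return total


def summarize_individuals(segments: Iterable[ROHSegment],
                          g: GenotypeMatrix) -> List[IndividualROHSummary]:
    """One summary per sample in ``g`` (zero-ROH samples included)."""
    known = set(g.samples)
    per_sample: dict = {sid: [] for sid in g.samples}
    for seg in segments:
        if seg.sample_id not in known:
            raise ValueError(f"segment references unknown sample {seg.sample_id!r}")
        per_sample[seg.sample_id].append(seg)
    covered = covered_autosome_length(g)
    out = []
    for sid in g.samples:
        segs = per_sample[sid]
        by_len = {c: 0 for c in SIZE_CLASSES}
        by_cnt = {c: 0 for c in SIZE_CLASSES}
        for s in segs:
            by_len[s.size_class] += s.length_bp
            by_cnt[s.size_class] += 1
        total = sum(by_len.values())
        out.append(IndividualROHSummary(
            sample_id=sid, n_roh=len(segs), total_length_bp=total,
            length_by_class=by_len, count_by_class=by_cnt,
            froh=total / covered if covered else 0.0))
    return out


def summaries_to_frame(summaries: Iterable[IndividualROHSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"sample": s.sample_id, "n_roh": s.n_roh,
               "total_length_bp": s.total_length_bp, "froh": s.froh}
        for c in SIZE_CLASSES:
            row[f"n_{c.lower()}"] = s.count_by_class[c]
            row[f"bp_{c.lower()}"] = s.length_by_class[c]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_chromosomes(segments: Iterable[ROHSegment],
                          chromosomes: Optional[Iterable[int]] = None) -> pd.DataFrame:
    """ROH count and total length per chromosome, sorted by chromosome."""
    counts: dict = {}
    lengths: dict = {}
    for seg in segments:
        counts[seg.chrom] = counts.get(seg.chrom, 0) + 1
        lengths[seg.chrom] = lengths.get(seg.chrom, 0) + seg.length_bp
    chroms = sorted(set(counts) | set(chromosomes or ()))
    return pd.DataFrame({
        "chrom": chroms,
        "n_roh": [counts.get(c, 0) for c in chroms],
        "total_length_bp": [lengths.get(c, 0) for c in chroms],
    })


def summarize_classes(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """Count and total length (Mb) per size class."""
    segs = list(segments)
    rows = []
    for c in SIZE_CLASSES:
        sub = [s for s in segs if s.size_class == c]
        rows.append({"class": c, "n_roh": len(sub),
                     "total_length_mb": sum(s.length_bp for s in sub) / 1e6})
    return pd.DataFrame(rows)


def genome_union_length(segments: Iterable[ROHSegment]) -> int:
    """Total bp covered by the union of all segments across individuals."""
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append((s.start_bp, s.end_bp))
    total = 0
    for intervals in by_chrom.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for a, b in intervals[1:]:
            if a <= cur_e + 1:
                cur_e = max(cur_e, b)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = a, b
        total += cur_e - cur_s + 1
    return total


def count_length_correlation(summaries: Iterable[IndividualROHSummary],
                             by_class: Optional[str] = None):
    """Pearson r (and two-sided t-based p) between per-individual ROH count
    and total length, optionally restricted to one size class."""
    summaries = list(summaries)
    if by_class is None:
        counts = np.array([s.n_roh for s in summaries], dtype=float)
        lengths = np.array([s.total_length_bp for s in summaries], dtype=float)
    else:
        if by_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {by_class!r}")
        counts = np.array([s.count_by_class[by_class] for s in summaries], dtype=float)
        lengths = np.array([s.length_by_class[by_class] for s in summaries], dtype=float)
    if len(summaries) < 3:
        raise ValueError("need at least 3 individuals")
    if counts.std() == 0 or lengths.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(counts, lengths)
    return float(r), float(p)
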