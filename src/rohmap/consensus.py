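"""Population-level ROH structure: incidence, islands and consensus regions.

*Incidence* counts, per SNP, how many individuals carry an ROH spanning it.
*Islands* are maximal runs of SNPs whose incidence rate strictly exceeds a
threshold (default 0.2), merged across short physical gaps.  *Consensus
ROH* pools overlapping segments across individuals (single-linkage on
intervals, per chromosome) and reports each pool's intersection interval —
the PLINK ``--homozyg-group`` consensus — keeping regions with at least
five SNPs.

Carrier status for a consensus region requires an ROH fully covering the
region's interval; since the interval is the intersection of pool member
segments, pool members are carriers by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .scanner import ROHSegment


@dataclass(frozen=True)
class ConsensusROH:
    """Intersection interval of a pool of overlapping ROH."""

    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    carrier_ids: tuple
    frequency: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def name(self) -> str:
        return f"chr{self.chrom}:{self.start_bp}-{self.end_bp}"


def snp_incidence(segments: Iterable[ROHSegment], g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP carrier counts and rates (columns chrom, pos, n_carriers, rate).

    A sample carries a SNP iff one of its ROH spans the SNP position; a
    sample's segments never overlap, so segment spans add directly.
    """
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    counts = np.zeros(len(positions), dtype=np.int64)
    offsets = {}
    pos_by_chrom = {}
    for chrom in g.chromosomes():
        idx = np.flatnonzero(chroms == chrom)
        offsets[chrom] = idx[0] if idx.size else 0
        pos_by_chrom[chrom] = positions[idx]
    diff = np.zeros(len(positions) + 1, dtype=np.int64)
    for seg in segments:
        pos = pos_by_chrom.get(seg.chrom)
        if pos is None or pos.size == 0:
            continue
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        if hi > lo:
            diff[offsets[seg.chrom] + lo] += 1
            diff[offsets[seg.chrom] + hi] -= 1
    counts = np.cumsum(diff[:-1])
    return pd.DataFrame({"chrom": chroms, "pos": positions,
                         "n_carriers": counts,
                         "rate": counts / g.n_samples})


def find_islands(track: pd.DataFrame, rate_threshold: float = 0.2,
                 max_gap_bp: int = 100_000) -> pd.DataFrame:
    """Maximal runs of SNPs with incidence rate strictly above the threshold.

    Above-threshold SNPs within ``max_gap_bp`` of each other (in bp) join
    the same island regardless of intervening below-threshold SNPs.
    Returns columns chrom, start_bp, end_bp, n_snps, max_rate.
    """
    if track.empty:
        raise ValueError("empty incidence track")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        hot = sub[sub["rate"] > rate_threshold]
        if hot.empty:
            continue
        pos = hot["pos"].to_numpy()
        rate = hot["rate"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, pos.size]):
            rows.append({"chrom": int(chrom), "start_bp": int(pos[lo]),
                         "end_bp": int(pos[hi - 1]), "n_snps": int(hi - lo),
                         "max_rate": float(rate[lo:hi].max())})
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "max_rate"])


def _pool_segments(segs: List[ROHSegment]):
    """Single-linkage pools by positional overlap; segs sorted by start.

    Each pool is then reduced to sub-pools with a non-empty intersection,
    split greedily left to right when the running intersection would empty.
    Yields (start, end) intersection intervals.
    """
    pools = []
    cur: List[ROHSegment] = []
    cur_max_end = -1
    for s in segs:
        if cur and s.start_bp <= cur_max_end:
            cur.append(s)
            cur_max_end = max(cur_max_end, s.end_bp)
        else:
            if cur:
                pools.append(cur)
            cur = [s]
            cur_max_end = s.end_bp
    if cur:
        pools.append(cur)

    intervals = []
    for pool in pools:
        i_start, i_end = pool[0].start_bp, pool[0].end_bp
        for s in pool[1:]:
            ns, ne = max(i_start, s.start_bp), min(i_end, s.end_bp)
            if ns > ne:
                intervals.append((i_start, i_end))
                i_start, i_end = s.start_bp, s.end_bp
            else:
                i_start, i_end = ns, ne
        intervals.append((i_start, i_end))
    return intervals


def build_consensus(segments: Iterable[ROHSegment], g: GenotypeMatrix,
                    min_snps: int = 5) -> List[ConsensusROH]:
    """Consensus ROH regions (pool intersections) with >= ``min_snps`` SNPs.

    Carrier sets are evaluated against the final interval (full coverage),
    so ``frequency`` always equals the population mean of
    :func:`carrier_status`.
    """
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: List[ConsensusROH] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp))
        pos = g.variant_positions(chrom)
        for start, end in _pool_segments(segs):
            n_inside = int(np.searchsorted(pos, end, side="right")
                           - np.searchsorted(pos, start, side="left"))
            if n_inside < min_snps:
                continue
            carriers = sorted({s.sample_id for s in segs if s.covers(start, end)})
            out.append(ConsensusROH(chrom=chrom, start_bp=int(start),
                                    end_bp=int(end), n_snps=n_inside,
                                    carrier_ids=tuple(carriers),
                                    frequency=len(carriers) / g.n_samples))
    return out


def carrier_status(consensus: ConsensusROH, segments: Iterable[ROHSegment],
                   sample_id: str) -> bool:
    """True iff the sample has an ROH fully covering the consensus interval."""
    return any(s.sample_id == sample_id and s.chrom == consensus.chrom
               and s.covers(consensus.start_bp, consensus.end_bp)
               for s in segments)


def carrier_matrix(consensus_list: Sequence[ConsensusROH],
                   g: GenotypeMatrix) -> pd.DataFrame:
    """Samples x regions boolean carrier table from stored carrier sets."""
    data = {c.name: pd.Series(False, index=g.samples) for c in consensus_list}
    df = pd.DataFrame(data)
    for c in consensus_list:
        df.loc[list(c.carrier_ids), c.name] = True
    return df


def consensus_to_frame(consensus_list: Iterable[ConsensusROH]) -> pd.DataFrame:
    rows = [{"chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
             "n_snps": c.n_snps, "n_carriers": len(c.carrier_ids),
             "frequency": c.frequency,
             "carriers": ",".join(c.carrier_ids)} for c in consensus_list]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps",
                                       "n_carriers", "frequency", "carriers"])


def to_bed(df: pd.DataFrame, path) -> None:
    """Write intervals as BED (0-based half-open, converted from 1-based
    inclusive internal coordinates)."""
    with open(path, "w") as fh:
        for r in df.to_dict("records"):
            fh.write(f"{r['chrom']}\t{r['start_bp'] - 1}\t{r['end_bp']}\n")
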