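"""PLINK-dialect genotype I/O and quality control.

Genotypes are held as a dense ``int8`` dosage matrix (individuals x SNPs)
coded 0 = homozygous for allele A, 1 = heterozygous, 2 = homozygous for
allele B, :data:`MISSING` (= -1) for no-calls.  The variant map is a pandas
DataFrame sorted by (chromosome, position); coordinates are 1-based and
intervals are inclusive throughout, matching the PLINK text formats.

Quality control applies the standard SNP-array filters in a fixed order
(autosome restriction, individual call rate, variant missingness, minor
allele frequency, Hardy-Weinberg exact test) with strict thresholds:
a sample at exactly 95 % call rate is removed, a variant at exactly
MAF 0.05 is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Missing genotype code in the calls matrix.
MISSING: int = -1

#: Cattle autosomes; PLINK's cow dialect codes X as 30, Y as 31, MT as 33.
AUTOSOMES = frozenset(range(1, 30))

_CHROM_CODES = {"X": 30, "Y": 31, "XY": 32, "MT": 33, "M": 33}

VARIANT_COLUMNS = ["id", "chrom", "cm", "pos", "allele_a", "allele_b"]


class FormatError(ValueError):
    """Raised for malformed PED/MAP/BED/BIM/FAM input."""


def _parse_chrom(token: str) -> int:
    token = token.strip()
    if token.upper() in _CHROM_CODES:
        return _CHROM_CODES[token.upper()]
    try:
        return int(token)
    except ValueError as exc:
        raise FormatError(f"unrecognised chromosome code {token!r}") from exc


@dataclass
class GenotypeMatrix:
    """Dosage-coded genotype calls with an aligned variant map.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (``FID_IID`` collapses to IID when the
        family id is uninformative; we store the IID column).
    variants : pandas.DataFrame
        One row per SNP with columns ``id, chrom, cm, pos, allele_a,
        allele_b``, sorted by (chrom, pos).
    calls : numpy.ndarray of int8, shape (n_samples, n_variants)
        Allele-B dosage, :data:`MISSING` for no-calls.
    """

    samples: list
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_positions(self, chrom: int) -> np.ndarray:
        """Base-pair positions of the SNPs on one chromosome."""
        return self.variants.loc[self.variants["chrom"] == chrom, "pos"].to_numpy()

    def chromosomes(self) -> list:
        """Chromosome codes present, in sorted order."""
        return sorted(self.variants["chrom"].unique().tolist())

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    def sort_variants(self) -> "GenotypeMatrix":
        order = np.lexsort((self.variants["pos"].to_numpy(),
                            self.variants["chrom"].to_numpy()))
        return self.subset(variant_idx=order)


@dataclass
class QCReport:
    """Per-filter removal accounting for :func:`apply_qc`."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_variants_in: int = 0
    n_variants_out: int = 0
    removed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("non_autosomal", "sample_call_rate", "variant_missingness",
                    "maf", "hwe"):
            self.removed.setdefault(key, 0)

    def validate(self) -> None:
        variant_removed = (self.removed["non_autosomal"]
                           + self.removed["variant_missingness"]
                           + self.removed["maf"] + self.removed["hwe"])
        assert self.n_variants_in - variant_removed == self.n_variants_out
        assert self.n_samples_in - self.removed["sample_call_rate"] == self.n_samples_out

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_in", self.n_samples_in),
                ("samples_out", self.n_samples_out),
                ("variants_in", self.n_variants_in),
                ("variants_out", self.n_variants_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        return pd.DataFrame(rows, columns=["metric", "count"])


# ---------------------------------------------------------------------------
# PED/MAP text dialect
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK .map file (chrom, id, cM, bp; 3-column files get cM=0)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, vid, cm, pos = parts
            elif len(parts) == 3:
                chrom, vid, pos = parts
                cm = "0"
            else:
                raise FormatError(f"{map_path}:{lineno}: expected 3 or 4 columns, "
                                  f"got {len(parts)}")
            rows.append((vid, _parse_chrom(chrom), float(cm), int(pos)))
    df = pd.DataFrame(rows, columns=["id", "chrom", "cm", "pos"])
    dup = df["id"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate variant id {df.loc[dup, 'id'].iloc[0]!r} in {map_path}")
    return df


def read_pedmap(ped_path, map_path, ref_alleles: dict | None = None) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    Allele A is the lexicographically smaller allele code observed for a
    variant (so the orientation does not depend on sample order); for a
    monomorphic variant the observed allele is taken as allele B, its
    counterpart being unknowable from the file.  ``ref_alleles`` (variant
    id -> allele-A code) overrides both rules where supplied.  Dosage
    counts allele B; "0 0" codes a missing genotype.  Variants are sorted
    by (chrom, pos) after loading.
    """
    vmap = read_map(map_path)
    m = len(vmap)
    samples: list = []
    geno_rows: list = []
    observed: list = [set() for _ in range(m)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"({m} variants), got {len(parts)}")
            iid = parts[1]
            samples.append(iid)
            row = parts[6:]
            geno_rows.append(row)
            for vi in range(m):
                for al in (row[2 * vi], row[2 * vi + 1]):
                    if al != "0":
                        observed[vi].add(al)
    ref_alleles = ref_alleles or {}
    alleles = []
    for vi, obs in enumerate(observed):
        vid = vmap["id"].iloc[vi]
        if len(obs) > 2:
            raise FormatError(f"{ped_path}: variant {vid} has "
                              f"more than two alleles ({sorted(obs)})")
        ref = ref_alleles.get(vid)
        if ref is not None:
            others = sorted(obs - {ref})
            if len(others) > 1:
                raise FormatError(f"{ped_path}: variant {vid}: alleles {sorted(obs)} "
                                  f"incompatible with reference allele {ref}")
            ordered = [ref, others[0] if others else "0"]
        else:
            ordered = sorted(obs)
            if len(ordered) == 1:
                # monomorphic: the observed allele is allele B (dose 2),
                # the unobserved counterpart is unknown
                ordered = ["0"] + ordered
        alleles.append((ordered + ["0", "0"])[:2])
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for si, row in enumerate(geno_rows):
        for vi in range(m):
            a1, a2 = row[2 * vi], row[2 * vi + 1]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise FormatError(
                        f"{ped_path}: sample {samples[si]} variant "
                        f"{vmap['id'].iloc[vi]}: half-missing genotype {a1}/{a2}")
                continue
            calls[si, vi] = (int(a1 == alleles[vi][1])
                             + int(a2 == alleles[vi][1]))
    vmap["allele_a"] = [a for a, _ in alleles]
    vmap["allele_b"] = [b for _, b in alleles]
    return GenotypeMatrix(samples=samples, variants=vmap, calls=calls).sort_variants()


def write_pedmap(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; alleles fall back to A/B codes where unobserved."""
    with open(map_path, "w") as fh:
        for row in g.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t{row.cm:g}\t{row.pos}\n")
    aa = g.variants.get("allele_a", pd.Series(["A"] * g.n_variants)).to_numpy()
    ab = g.variants.get("allele_b", pd.Series(["B"] * g.n_variants)).to_numpy()
    aa = np.where(aa == "0", "A", aa)
    ab = np.where(ab == "0", "B", ab)
    code = {0: lambda i: (aa[i], aa[i]), 1: lambda i: (aa[i], ab[i]),
            2: lambda i: (ab[i], ab[i]), MISSING: lambda i: ("0", "0")}
    with open(ped_path, "w") as fh:
        for si, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for vi in range(g.n_variants):
                fields.extend(code[int(g.calls[si, vi])](vi))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary dialect (SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit PLINK codes, pairs of bits little-endian within a byte:
# 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2
_BITS_TO_DOSE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSE_TO_BITS = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_bedset(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK binary fileset (SNP-major .bed with .bim/.fam)."""
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    samples = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise FormatError(f"{bim_path}: expected 6 columns, got {bim.shape[1]}")
    vmap = pd.DataFrame({
        "id": bim.iloc[:, 1],
        "chrom": [_parse_chrom(c) for c in bim.iloc[:, 0]],
        "cm": bim.iloc[:, 2].astype(float),
        "pos": bim.iloc[:, 3].astype(int),
        "allele_a": bim.iloc[:, 4],
        "allele_b": bim.iloc[:, 5],
    })[VARIANT_COLUMNS]
    if vmap["id"].duplicated().any():
        raise FormatError(f"duplicate variant id in {bim_path}")
    n, m = len(samples), len(vmap)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic/mode bytes {raw[:3].hex()} "
                          f"(want {_BED_MAGIC.hex()}: SNP-major bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(f"{bed_path}: size {len(raw)} != expected {expected} "
                          f"for {n} samples x {m} variants")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, little-endian pairs within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (data[:, :, None] >> shifts) & 0b11           # (m, bps, 4)
    two_bit = two_bit.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _BITS_TO_DOSE[two_bit].T                        # (n, m)
    return GenotypeMatrix(samples=samples, variants=vmap,
                          calls=np.ascontiguousarray(calls)).sort_variants()


def write_bedset(g: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    """Write a PLINK binary fileset (SNP-major)."""
    with open(fam_path, "w") as fh:
        for sid in g.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    aa = np.where(g.variants["allele_a"].to_numpy() == "0", "A",
                  g.variants["allele_a"].to_numpy())
    ab = np.where(g.variants["allele_b"].to_numpy() == "0", "B",
                  g.variants["allele_b"].to_numpy())
    with open(bim_path, "w") as fh:
        for vi, row in enumerate(g.variants.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.id}\t{row.cm:g}\t{row.pos}\t{aa[vi]}\t{ab[vi]}\n")
    n, m = g.n_samples, g.n_variants
    bytes_per_snp = (n + 3) // 4
    bits = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    dose_bits = np.empty_like(g.calls, dtype=np.uint8)
    for dose, bb in _DOSE_TO_BITS.items():
        dose_bits[g.calls == dose] = bb
    bits[:, :n] = dose_bits.T
    packed = (bits.reshape(m, bytes_per_snp, 4)
              << np.array([0, 2, 4, 6], dtype=np.uint8)).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one.  Returns 1
    for monomorphic input (no test possible).
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (gammaln(n + 1) - gammaln(hom_rare + 1) - gammaln(hets + 1)
            - gammaln(hom_common + 1) + hets * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed = prob[hets == n_het][0]
    p = prob[prob <= observed * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def genotype_counts(calls: np.ndarray):
    """Per-variant (hom A, het, hom B, missing) counts for a calls matrix."""
    hom_a = (calls == 0).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    hom_b = (calls == 2).sum(axis=0)
    miss = (calls == MISSING).sum(axis=0)
    return hom_a, het, hom_b, miss


def apply_qc(g: GenotypeMatrix,
             sample_call_rate: float = 0.95,
             max_variant_missing: float = 0.05,
             min_maf: float = 0.05,
             hwe_p_floor: float = 1e-6):
    """Apply the array QC filters; returns (filtered matrix, QCReport).

    Filter order: (1) non-autosomal variants, (2) samples with call rate
    <= ``sample_call_rate``, (3) variants with missingness >=
    ``max_variant_missing``, (4) variants with MAF <= ``min_maf``,
    (5) variants with HWE exact p <= ``hwe_p_floor``.  All comparisons are
    strict: boundary values are removed.
    """
    if g.n_samples == 0 or g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_samples_in=g.n_samples, n_variants_in=g.n_variants)

    autosomal = g.variants["chrom"].isin(AUTOSOMES).to_numpy()
    report.removed["non_autosomal"] = int((~autosomal).sum())
    g = g.subset(variant_idx=np.flatnonzero(autosomal))
    if g.n_variants == 0:
        raise ValueError("QC removed all variants (dominant filter: non_autosomal)")

    call_rate = (g.calls != MISSING).mean(axis=1)
    keep_s = call_rate > sample_call_rate
    report.removed["sample_call_rate"] = int((~keep_s).sum())
    g = g.subset(sample_idx=np.flatnonzero(keep_s))
    if g.n_samples == 0:
        raise ValueError("QC removed all samples (dominant filter: sample_call_rate)")

    hom_a, het, hom_b, miss = genotype_counts(g.calls)
    n_called = hom_a + het + hom_b
    missing_rate = miss / g.n_samples
    keep_miss = missing_rate < max_variant_missing
    report.removed["variant_missingness"] = int((~keep_miss).sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0, (het + 2 * hom_b) / (2 * n_called), 0.0)
    maf = np.minimum(freq_b, 1 - freq_b)
    keep_maf = keep_miss & (maf > min_maf)
    report.removed["maf"] = int((keep_miss & ~(maf > min_maf)).sum())

    keep = keep_maf.copy()
    n_hwe_removed = 0
    for vi in np.flatnonzero(keep_maf):
        p = hwe_exact_test(int(hom_a[vi]), int(het[vi]), int(hom_b[vi]))
        if p <= hwe_p_floor:
            keep[vi] = False
            n_hwe_removed += 1
    report.removed["hwe"] = n_hwe_removed

    if not keep.any():
        dominant = max(("variant_missingness", "maf", "hwe"),
                       key=lambda k: report.removed[k])
        raise ValueError(f"QC removed all variants (dominant filter: {dominant})")
    g = g.subset(variant_idx=np.flatnonzero(keep))
    report.n_samples_out = g.n_samples
    report.n_variants_out = g.n_variants
    report.validate()
    logger.info("QC kept %d/%d samples, %d/%d variants",
                report.n_samples_out, report.n_samples_in,
                report.n_variants_out, report.n_variants_in)
    return g, report
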