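"""Synthetic SNP-array genotypes with planted autozygous segments, and
phenotypes generated under the mixed model the pipeline fits.

The generator emulates the structure the analysis assumes, not a
coalescent history:

* biallelic autosomal SNPs at array density (mean spacing 4 kb, matching a
  high-density bovine array), allele-B frequencies Uniform(0.05, 0.5);
* Hardy-Weinberg genotypes outside planted segments;
* per-individual autozygous segments planted directly: counts Poisson with
  mean set so the expected genomic inbreeding (FROH) matches a target
  (default 0.047), lengths from a short/long log-normal mixture (modes
  near 0.7 Mb and 6 Mb, 85 % short) mirroring the predominance of small
  ROH over rare large ones; inside a segment the individual is homozygous
  (allele drawn once per SNP by its frequency);
* genotyping error (heterozygote calls inside segments) and missingness;
* optional association regions: intervals where a chosen fraction of
  individuals carries an autozygous segment, with a trait effect;
* phenotypes y = fixed effects + region effects x carrier + polygenic term
  with covariance G sigma_g^2 (G from the realised genotypes, small ridge
  for factorisation) + N(0, sigma_e^2) noise.

Everything is driven by one integer seed; identical seeds give identical
outputs.  The truth tables emitted alongside allow exact recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_pedmap
from .mixed_model import build_grm
from .phenotypes import TRAITS


@dataclass(frozen=True)
class AssociationRegion:
    """A planted carrier interval with a trait effect (trait units)."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_freq: float
    effect: float
    trait: str = "CW"


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_samples: int = 60
    n_chromosomes: int = 3
    snps_per_chromosome: int = 2000
    mean_spacing_bp: float = 4000.0
    maf_range: Tuple[float, float] = (0.05, 0.5)
    target_froh: Optional[float] = 0.047
    segments_per_individual: Optional[float] = None  # Poisson mean; overrides target_froh
    short_length_log_mean: float = np.log(700_000.0)
    short_length_log_sd: float = 0.25
    long_length_log_mean: float = np.log(6_000_000.0)
    long_length_log_sd: float = 0.30
    short_weight: float = 0.85
    het_error_rate: float = 0.0
    missing_rate: float = 0.0
    association_regions: Tuple[AssociationRegion, ...] = ()
    n_farms: int = 2
    n_years: int = 3
    sigma_g2: float = 1.0
    sigma_e2: float = 1.0

    def mean_segment_length(self) -> float:
        short = np.exp(self.short_length_log_mean + self.short_length_log_sd ** 2 / 2)
        long = np.exp(self.long_length_log_mean + self.long_length_log_sd ** 2 / 2)
        return self.short_weight * short + (1 - self.short_weight) * long


@dataclass
class SimTruth:
    """Ground truth emitted with the simulated data."""

    planted: pd.DataFrame          # sample, chrom, start_bp, end_bp, kind
    region_carriers: dict          # region name -> list of sample ids
    regions: List[AssociationRegion]
    fixed_effects: dict = field(default_factory=dict)
    polygenic: Optional[pd.DataFrame] = None


def _segment_rate(config: SimConfig, covered_bp: float) -> float:
    if config.segments_per_individual is not None:
        return config.segments_per_individual
    if config.target_froh is None:
        return 0.0
    return config.target_froh * covered_bp / config.mean_segment_length()


def simulate_genotypes(config: SimConfig):
    """Generate (GenotypeMatrix, SimTruth) under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    n, c, m = config.n_samples, config.n_chromosomes, config.snps_per_chromosome
    # positions: exponential spacings around the mean, 1-based
    chroms = np.repeat(np.arange(1, c + 1), m)
    positions = np.empty(c * m, dtype=np.int64)
    for ci in range(c):
        gaps = np.maximum(1, rng.exponential(config.mean_spacing_bp, size=m)).astype(np.int64)
        positions[ci * m:(ci + 1) * m] = np.cumsum(gaps) + 1
    freqs = rng.uniform(*config.maf_range, size=c * m)
    calls = rng.binomial(2, freqs, size=(n, c * m)).astype(np.int8)

    chrom_spans = {}
    for ci in range(1, c + 1):
        pos = positions[chroms == ci]
        chrom_spans[ci] = (int(pos[0]), int(pos[-1]))
    covered = float(sum(e - s + 1 for s, e in chrom_spans.values()))
    seg_rate = _segment_rate(config, covered)

    samples = [f"S{i:04d}" for i in range(n)]
    planted_rows = []

    def plant(si: int, chrom: int, start: int, end: int, kind: str) -> None:
        cmask = chroms == chrom
        pos = positions[cmask]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        if hi <= lo:
            return
        idx = np.flatnonzero(cmask)[lo:hi]
        hom = 2 * rng.binomial(1, freqs[idx]).astype(np.int8)
        calls[si, idx] = hom
        planted_rows.append({"sample": samples[si], "chrom": chrom,
                             "start_bp": int(pos[lo]), "end_bp": int(pos[hi - 1]),
                             "kind": kind})

    # background autozygous segments
    span_weights = np.array([chrom_spans[ci][1] - chrom_spans[ci][0] + 1
                             for ci in range(1, c + 1)], dtype=float)
    span_weights /= span_weights.sum()
    for si in range(n):
        for _ in range(rng.poisson(seg_rate)):
            chrom = int(rng.choice(np.arange(1, c + 1), p=span_weights))
            if rng.random() < config.short_weight:
                length = rng.lognormal(config.short_length_log_mean,
                                       config.short_length_log_sd)
            else:
                length = rng.lognormal(config.long_length_log_mean,
                                       config.long_length_log_sd)
            s0, e0 = chrom_spans[chrom]
            length = min(int(length), e0 - s0)
            start = int(rng.integers(s0, max(s0 + 1, e0 - length)))
            plant(si, chrom, start, start + length, "background")

    # association regions: fixed carrier fraction, chosen without replacement
    region_carriers = {}
    for region in config.association_regions:
        s0, e0 = chrom_spans.get(region.chrom, (None, None))
        if s0 is None or region.start_bp < s0 or region.end_bp > e0:
            raise ValueError(f"association region {region} outside the "
                             f"SNP-covered span {chrom_spans.get(region.chrom)}")
        k = int(round(region.carrier_freq * n))
        carriers = rng.choice(n, size=k, replace=False)
        name = f"chr{region.chrom}:{region.start_bp}-{region.end_bp}"
        region_carriers[name] = sorted(samples[i] for i in carriers)
        for si in carriers:
            plant(int(si), region.chrom, region.start_bp, region.end_bp, "region")

    # genotyping error and missingness
    if config.het_error_rate > 0 and planted_rows:
        for row in planted_rows:
            cmask = chroms == row["chrom"]
            pos = positions[cmask]
            lo = int(np.searchsorted(pos, row["start_bp"], side="left"))
            hi = int(np.searchsorted(pos, row["end_bp"], side="right"))
            idx = np.flatnonzero(cmask)[lo:hi]
            si = samples.index(row["sample"])
            err = rng.random(idx.size) < config.het_error_rate
            calls[si, idx[err]] = 1
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    variants = pd.DataFrame({
        "id": [f"snp{ci}_{i}" for ci, i in zip(chroms, np.tile(np.arange(m), c))],
        "chrom": chroms, "cm": 0.0, "pos": positions,
        "allele_a": "A", "allele_b": "B"})
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    truth = SimTruth(
        planted=pd.DataFrame(planted_rows,
                             columns=["sample", "chrom", "start_bp", "end_bp", "kind"]),
        region_carriers=region_carriers,
        regions=list(config.association_regions))
    return g, truth


def simulate_phenotypes(g: GenotypeMatrix, truth: SimTruth, config: SimConfig,
                        traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Phenotype table for the simulated animals.

    Each trait is generated as fixed effects + planted region effects +
    polygenic term (covariance G sigma_g^2) + residual noise.  Trait scales
    follow the recorded units: weights in kg, ADG in kg/day; region
    effects from the config are added on the trait they target.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = g.n_samples
    farm = rng.integers(0, config.n_farms, size=n)
    year = rng.integers(0, config.n_years, size=n)
    sex = rng.integers(0, 2, size=n)
    weight0 = rng.normal(250.0, 20.0, size=n)
    days = np.round(rng.normal(300.0, 25.0, size=n)).astype(int)
    days = np.maximum(days, 100)

    farm_eff = rng.normal(0.0, 1.0, size=config.n_farms)
    year_eff = rng.normal(0.0, 1.0, size=config.n_years)
    sex_eff = np.array([0.0, 1.5])
    b_weight, b_days = 0.05, 0.02
    base = (farm_eff[farm] + year_eff[year] + sex_eff[sex]
            + b_weight * weight0 + b_days * days)

    # polygenic factor shared across traits' independent draws
    grm = build_grm(g)
    ridge = 1e-6 * np.trace(grm.matrix) / n
    L = np.linalg.cholesky(grm.matrix + ridge * np.eye(n))

    table = pd.DataFrame({
        "sample": g.samples,
        "farm": [f"farm{i}" for i in farm],
        "year": [str(2008 + i) for i in year],
        "sex": np.where(sex == 0, "F", "M"),
        "weight_before_fattening": np.round(weight0, 2),
        "fattening_days": days,
    })
    polygenic = {}
    carrier_ind = {name: np.array([s in set(ids) for s in g.samples], dtype=float)
                   for name, ids in truth.region_carriers.items()}
    for trait in traits:
        u = np.sqrt(config.sigma_g2) * (L @ rng.standard_normal(n))
        e = np.sqrt(config.sigma_e2) * rng.standard_normal(n)
        y = base + u + e
        for region in truth.regions:
            if region.trait == trait:
                name = f"chr{region.chrom}:{region.start_bp}-{region.end_bp}"
                y = y + region.effect * carrier_ind[name]
        table[trait] = np.round(y, 4)
        polygenic[trait] = u
    if "ADG" in table.columns:
        table["end_weight"] = np.round(
            table["weight_before_fattening"] + table["ADG"] * table["fattening_days"], 2)
    truth.fixed_effects = {"farm": farm_eff.tolist(), "year": year_eff.tolist(),
                           "sex": sex_eff.tolist(),
                           "weight_before_fattening": b_weight,
                           "fattening_days": b_days}
    truth.polygenic = pd.DataFrame(polygenic, index=g.samples)
    return table


FIXTURE_SIZES = {
    "small": dict(n_samples=60, n_chromosomes=3, snps_per_chromosome=2000),
    "medium": dict(n_samples=600, n_chromosomes=5, snps_per_chromosome=10_000),
}


def end_to_end_fixture(size: str, out_dir, seed: int = 2021,
                       association_regions: Optional[Tuple[AssociationRegion, ...]] = None,
                       **overrides):
    """Write a complete PED/MAP + phenotype + truth fixture to ``out_dir``.

    "small" is 60 samples x 3 chromosomes x 2,000 SNPs (seconds);
    "medium" is 600 samples x 5 chromosomes x 10,000 SNPs.
    Returns (config, GenotypeMatrix, SimTruth, phenotype table).
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    params = dict(FIXTURE_SIZES[size])
    params.update(overrides)
    if association_regions:
        params["association_regions"] = tuple(association_regions)
    config = SimConfig(seed=seed, **params)
    g, truth = simulate_genotypes(config)
    pheno = simulate_phenotypes(g, truth, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedmap(g, out / "sim.ped", out / "sim.map")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    truth.planted.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
    carrier_rows = [{"region": name, "sample": sid}
                    for name, ids in truth.region_carriers.items() for sid in ids]
    pd.DataFrame(carrier_rows, columns=["region", "sample"]).to_csv(
        out / "truth_carriers.tsv", sep="\t", index=False)
    (out / "seed.txt").write_text(f"{seed}\n")
    return config, g, truth, pheno
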