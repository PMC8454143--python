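import numpy as np
import pandas as pd
import pytest

from rohmap import GenotypeMatrix, ScannerParams


def make_matrix(calls, spacing_bp=10_000, chrom=1, samples=None,
                start_bp=100_000):
    """GenotypeMatrix from a raw calls array with evenly spaced SNPs."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n, m = calls.shape
    samples = samples or [f"S{i}" for i in range(n)]
    pos = start_bp + spacing_bp * np.arange(m)
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(m)], "chrom": chrom, "cm": 0.0,
        "pos": pos, "allele_a": "A", "allele_b": "B"})
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture
def tight_params():
    """Scanner thresholds scaled to toy chromosomes (short windows/runs)."""
    return ScannerParams(window_snps=10, window_max_missing=2,
                         min_length_bp=50_000, min_snps=8,
                         min_density_bp_per_snp=50_000)


@pytest.fixture(scope="session")
def small_sim():
    """Session-shared small simulated dataset with planted segments."""
    from rohmap import SimConfig, simulate_genotypes
    config = SimConfig(seed=11, n_samples=40, n_chromosomes=2,
                       snps_per_chromosome=1500)
    g, truth = simulate_genotypes(config)
    return config, g, truth
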