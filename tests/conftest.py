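import numpy as np
import pandas as pd
import pytest

from xutclass import (
    CountMatrix,
    FeatureAnnotation,
    GenomicInterval,
    SimulationConfig,
    StrandedCoverage,
    simulate_annotation,
    simulate_netseq_counts,
)


@pytest.fixture
def toy_genes():
    return [
        FeatureAnnotation("g1", GenomicInterval("chrI", 100, 1000, "+"), "mRNA"),
        FeatureAnnotation("g2", GenomicInterval("chrI", 2000, 3200, "-"), "mRNA"),
        FeatureAnnotation("g3", GenomicInterval("chrII", 500, 1500, "+"), "mRNA"),
    ]


@pytest.fixture
def toy_xuts():
    return [
        FeatureAnnotation("x1", GenomicInterval("chrI", 500, 1500, "-"), "XUT"),
        FeatureAnnotation("x2", GenomicInterval("chrII", 1400, 2000, "-"), "XUT"),
    ]


@pytest.fixture
def chrom_sizes():
    return {"chrI": 5000, "chrII": 4000}


@pytest.fixture
def uniform_coverage(chrom_sizes):
    """Coverage of 2.0 on every position of both strands (normalized)."""
    cov = StrandedCoverage(
        plus={c: np.full(n, 2.0) for c, n in chrom_sizes.items()},
        minus={c: np.full(n, 2.0) for c, n in chrom_sizes.items()},
        library_size=float(sum(chrom_sizes.values()) * 4),
        normalized=True,
    )
    return cov


@pytest.fixture
def small_cfg():
    """Small simulated study for fast end-to-end tests."""
    return SimulationConfig(seed=7, genes_per_class=(12, 12, 12, 12))


@pytest.fixture
def small_dataset(small_cfg):
    genes, xuts, truth = simulate_annotation(small_cfg)
    cm, cov = simulate_netseq_counts(small_cfg, genes, xuts, truth, make_coverage=True)
    return small_cfg, genes, xuts, truth, cm, cov


def nb_counts(rng, mean, alpha, size):
    """Reference NB sampler with Var = mu + alpha mu^2 for test data."""
    if alpha == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


@pytest.fixture
def null_count_matrix():
    """2 vs 2 NB count matrix with no true difference (mean 200, alpha 0.05)."""
    rng = np.random.default_rng(42)
    counts = nb_counts(rng, 200.0, 0.05, size=(2000, 4))
    cond = {"WT_1": "WT", "WT_2": "WT", "mut_1": "mut", "mut_2": "mut"}
    return CountMatrix(pd.DataFrame(counts, columns=list(cond)), cond)
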