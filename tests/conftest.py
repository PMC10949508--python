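import numpy as np
import pytest

from fmodules import FitnessMatrix, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng) -> FitnessMatrix:
    """10 genes x 6 samples, fully observed."""
    return FitnessMatrix(
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(6)],
        values=rng.normal(size=(10, 6)),
    )


@pytest.fixture(scope="session")
def easy_synthetic():
    """Well-separated planted modules: K=5, no noise, no sharing."""
    cfg = SyntheticConfig(
        n_genes=400,
        n_samples=40,
        n_modules=5,
        noise_sd=0.0,
        shared_gene_fraction=0.0,
        seed=11,
    )
    return generate(cfg)


def pearson(x, y):
    """Textbook Pearson correlation, independent of the package."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
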