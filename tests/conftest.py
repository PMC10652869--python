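import numpy as np
import pytest

import ordgwas as og


@pytest.fixture(scope="session")
def small_panel() -> og.GenotypeMatrix:
    """60 lines x 300 markers, inbred-style, deterministic."""
    return og.synth_genotypes(n=60, m=300, seed=11)


@pytest.fixture(scope="session")
def panel_199() -> og.GenotypeMatrix:
    """Study-sized panel (199 lines) on a reduced 1,000-marker map."""
    return og.synth_genotypes(n=199, m=1000, seed=42)


@pytest.fixture
def tiny_tsv(tmp_path):
    """3-sample, 2-marker genotype TSV on disk."""
    path = tmp_path / "geno.tsv"
    path.write_text(
        "marker\tchrom\tpos\ts1\ts2\ts3\n"
        "m1\t1\t100\t0\t1\t2\n"
        "m2\t2\t250\t2\tNA\t0\n"
    )
    return path


def binary_fixture(n=20, seed=3):
    """Small deterministic (x, y01) pair with genuine association."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x -= x.mean()
    y = (x + rng.logistic(0, 1.5, n) > 0).astype(float)
    if y.min() == y.max():  # pragma: no cover — guard for odd seeds
        y[0] = 1 - y[0]
    return x, y


def ordinal_fixture(n=30, L=3, seed=5):
    """Small deterministic (x, OrdinalPhenotype) pair, proportional-odds truth."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x -= x.mean()
    latent = 0.8 * x + rng.logistic(0, 1, n)
    cuts = np.quantile(latent, np.arange(1, L) / L)
    levels = np.digitize(latent, cuts) + 1
    return x, og.OrdinalPhenotype(levels)
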