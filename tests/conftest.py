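import warnings

import numpy as np
import pandas as pd
import pytest

from peakcovar.core import EnrichmentMatrix, SampleMeta
from peakcovar.simulate import SimulationConfig


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def meta_4v4():
    cols = [f"CTRL_{i}" for i in range(4)] + [f"MS_{i}" for i in range(4)]
    return SampleMeta(pd.DataFrame({"group": ["CTRL"] * 4 + ["MS"] * 4}, index=cols))


@pytest.fixture
def small_sim_config():
    """Scaled-down study: every planted structure present, runs in ~0.1 s."""

    def make(seed, **overrides):
        base = dict(
            n_genes=800,
            n_broad_peaks=600,
            subpeaks_per_broad=(2, 4),
            depth=300_000,
            n_cluster_regions=40,
            n_de_regions=45,
        )
        base.update(overrides)
        return SimulationConfig(seed=seed, **base)

    return make


def nb_counts(rng, mu, alpha, shape):
    """NB draws with variance mu + alpha mu^2 (test helper)."""
    if alpha <= 0:
        return rng.poisson(np.broadcast_to(mu, shape))
    lam = rng.gamma(1.0 / alpha, np.broadcast_to(mu, shape) * alpha)
    return rng.poisson(lam)


@pytest.fixture
def nb_matrix_factory(meta_4v4):
    def make(seed, n_regions=200, mu=300.0, alpha=0.05, fc_test=1.0):
        rng = np.random.default_rng(seed)
        cols = meta_4v4.sample_ids
        mus = np.tile([mu] * 4 + [mu * fc_test] * 4, (n_regions, 1))
        y = nb_counts(rng, mus, alpha, mus.shape)
        values = pd.DataFrame(y, columns=cols, index=[f"r{i:04d}" for i in range(n_regions)])
        return EnrichmentMatrix(values)

    return make
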