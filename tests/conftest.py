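import numpy as np
import pandas as pd
import pytest

import richtrend as rt
from richtrend.data_model import GenusAggregate


def linear_trend_aggregate(seed=0, n_genera=40, n_samples=20, slope=0.8,
                           intercept=1.0, noise=0.1, spike=None,
                           logy_range=(2.0, 9.0)) -> GenusAggregate:
    """Aggregate whose detected cells satisfy log n = a + b log y + eps,
    optionally with genus 0 offset by ``spike``."""
    rng = np.random.default_rng(seed)
    logy = rng.uniform(*logy_range, size=(n_genera, n_samples))
    z = intercept + slope * logy + rng.normal(0, noise, size=(n_genera, n_samples))
    if spike is not None:
        z[0] += spike
    y = np.exp(logy)
    n = np.exp(z)
    gids = [f"g{i:02d}" for i in range(n_genera)]
    sids = [f"s{j:02d}" for j in range(n_samples)]
    return GenusAggregate(n=pd.DataFrame(n, index=gids, columns=sids),
                          y=pd.DataFrame(y, index=gids, columns=sids),
                          tau=pd.Series(y.sum(axis=0), index=sids))


@pytest.fixture()
def linear_agg_factory():
    return linear_trend_aggregate


@pytest.fixture(scope="session")
def small_scenario():
    """One modest null-richness survey reused by read-only tests."""
    return rt.null_richness_confounding_scenario(
        seed=11, n_genera=30, n_per_group=15, depth=2e4)


@pytest.fixture(scope="session")
def small_trend(small_scenario):
    return rt.fit_trend_spline(small_scenario["aggregate"])


@pytest.fixture()
def tiny_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text("taxon_id\tsampleA\tsampleB\n"
                    "t1\t5\t0\n"
                    "t2\t2\t1\n"
                    "t3\t0\t3\n")
    return path
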