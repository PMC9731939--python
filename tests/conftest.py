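"""Shared fixtures.

LFR graph sets at the study's hyperparameters (1000 nodes, tau1=3, tau2=2,
average degree 20, max degree 50) are expensive to generate, so they are
session-scoped and shared between the unit tests and the acceptance tests.
Seeds are fixed constants: the graphs are part of the study conditions.
"""

from __future__ import annotations

import pytest

from commexplain import LFRConfig, fixture_barbell, generate_lfr, generate_planted_partition

STUDY_LFR = dict(n=1000, tau1=3.0, tau2=2.0, avg_degree=20.0, max_degree=50)


def make_lfr_set(mu: float, count: int, base_seed: int = 42):
    """Generate `count` study-scale LFR graphs at mixing level `mu`."""
    graphs = []
    for i in range(count):
        cfg = LFRConfig(mu=mu, seed=base_seed + 101 * i, **STUDY_LFR)
        graphs.append(generate_lfr(cfg))
    return graphs


@pytest.fixture(scope="session")
def lfr_mu02():
    """20 LFR graphs at mu=0.2 (graph, ground-truth) pairs."""
    return make_lfr_set(0.2, 20)


@pytest.fixture(scope="session")
def lfr_mu03():
    """10 LFR graphs at mu=0.3."""
    return make_lfr_set(0.3, 10)


@pytest.fixture(scope="session")
def lfr_mu04():
    """20 LFR graphs at mu=0.4."""
    return make_lfr_set(0.4, 20)


@pytest.fixture(scope="session")
def barbell5():
    """Two 5-cliques joined by one bridge; every value checkable by hand."""
    return fixture_barbell(5)


@pytest.fixture(scope="session")
def planted60():
    """Connected 60-node planted-partition graph for oracle comparisons."""
    return generate_planted_partition(k=3, size=20, p_in=0.4, p_out=0.05, seed=7)
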