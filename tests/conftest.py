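import logging

import numpy as np
import pandas as pd
import pytest

import mortsmooth as ms
from mortsmooth.cmc import cmc

# short-chain fits in tests trip the (noisy) split-Rhat warning constantly
logging.getLogger("mortsmooth.smoothing").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def grid9():
    return ms.generate_adjacency(9, "grid", 0)


@pytest.fixture(scope="session")
def triangle():
    return ms.AdjacencyGraph.from_edges([1, 2, 3], [(1, 2), (2, 3), (3, 1)])


def flat_surface(graph, T, mu):
    """Constant surface at level mu (all components zero)."""
    n = graph.n
    return ms.TrueSurface(
        tuple(graph.nodes), mu, np.zeros(T), np.zeros(T), np.zeros(n),
        np.zeros(n), np.zeros((n, T)),
    )


def pooled_from_noise(graph, lam, V, rng, labels=None):
    """Pooled-estimate table: y = lam + noise, known variances."""
    n, T = lam.shape
    y = lam + rng.standard_normal((n, T)) * np.sqrt(V)
    rows = [
        dict(admin1=a, period=t,
             period_label=str(t) if labels is None else labels[t],
             logit_q=y[i, t], var_logit_q=float(np.asarray(V)[i, t]
                                                if np.ndim(V) else V),
             status="ok")
        for i, a in enumerate(graph.nodes)
        for t in range(T)
    ]
    return pd.DataFrame(rows), y


@pytest.fixture(scope="session")
def survey_world():
    """One simulated survey with known truth, reused by read-only tests."""
    graph = ms.generate_adjacency(4, "grid", 0)
    hyp = ms.SurfaceHypers(0.005, 0.02, 0.01, 0.02, 0.005)
    surf_u5 = ms.sample_true_surface(graph, 6, hyp, -3.0, 11)
    surf_514 = ms.sample_true_surface(graph, 6, hyp, -4.7, 12)
    breaks = [cmc(2018, 12) + 1 - 48 * k for k in range(6, -1, -1)]
    design = ms.default_design(
        graph.nodes, clusters_per_stratum=12, women_per_cluster=25, seed=13
    )
    records = ms.simulate_survey(
        {"u5": surf_u5, "5to14": surf_514}, design, breaks, cmc(2018, 12),
        fertility=0.015, seed=14, survey_id="svy2018",
    )
    return dict(
        graph=graph, surf_u5=surf_u5, surf_514=surf_514,
        breaks=breaks, design=design, records=records,
        interview=cmc(2018, 12),
    )
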