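import numpy as np
import pytest

import symptomnet as sn
from symptomnet.ggm import GGMConfig, GGMNetwork


@pytest.fixture(scope="session")
def planted_spec():
    return sn.default_network()


@pytest.fixture(scope="session")
def true_network(planted_spec):
    from symptomnet.synthetic import planted_weights
    P = planted_weights(planted_spec)
    return GGMNetwork(nodes=[f"item{k:02d}" for k in range(planted_spec.n_nodes)],
                      weights=P, n=0, estimator="truth", gamma=0.5)


@pytest.fixture(scope="session")
def cohort2000(planted_spec):
    return sn.generate_cohort(planted_spec, sn.default_cohort(n_subjects=2000, seed=11))


@pytest.fixture(scope="session")
def cohort400(planted_spec):
    return sn.generate_cohort(planted_spec, sn.default_cohort(n_subjects=400, seed=12))


@pytest.fixture()
def fast_config():
    """Reduced-path glasso config for bootstrap-heavy tests."""
    return GGMConfig(estimator="glasso", n_lambda=15)


@pytest.fixture(scope="session")
def small_weight_graphs():
    """Fixture set of signed weighted graphs with <= 6 nodes for oracle checks."""
    rng = np.random.default_rng(42)
    graphs = []
    for p in (3, 4, 5, 6):
        W = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        vals = rng.uniform(-0.4, 0.4, size=len(iu[0]))
        vals[rng.random(len(vals)) < 0.3] = 0.0
        W[iu] = vals
        W = W + W.T
        comm = rng.integers(1, 3, size=p)
        graphs.append((W, comm))
    return graphs
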