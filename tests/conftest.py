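import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pecircuit import (
    ConnectivitySpec,
    ModelParams,
    PopulationSpec,
    assign_preferred_stimuli,
    sample_connectivity,
)
from pecircuit.connectivity import _template_of
from pecircuit._numerics import softplus_inverse


@pytest.fixture(scope="session")
def pop_small():
    return PopulationSpec(n_pc=40, n_pv=8, n_som=10, n_vip=8, n_groups=4)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def conn_small(pop_small):
    return sample_connectivity(pop_small, ConnectivitySpec(), seed=7)


@pytest.fixture()
def bank_small(pop_small):
    return assign_preferred_stimuli(pop_small)


def homogenize_all_pathways(conn):
    """Force every pathway row to exactly its mean total strength.

    Together with a single selectivity group this makes every neuron of a
    population statistically identical, so grouped linear solutions are
    exact (used for oracle-equivalence tests).
    """
    out = conn.copy()
    for key, w in out.weights.items():
        spec = out.spec.pathways[_template_of(key)]
        mask = out.masks[key]
        counts = mask.sum(axis=1)
        w[...] = 0.0
        rows = counts > 0
        w[rows] = mask[rows] * (spec.mean_weight / counts[rows, None])
        if key in out.v_params:
            v = out.v_params[key]
            v[...] = 0.0
            v[mask & (w > 0)] = softplus_inverse(w[mask & (w > 0)])
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
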