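import numpy as np
import pytest

import circgat as cg


@pytest.fixture(scope="session")
def planted():
    """Default planted benchmark instance with its ontology and similarities."""
    model = cg.PlantedModel(seed=11)
    y = cg.generate_associations(model)
    dag = cg.generate_ontology(model)
    sims = cg.compute_all_similarities(y, dag)
    return {"model": model, "Y": y, "dag": dag, "sims": sims}


@pytest.fixture(scope="session")
def small_planted():
    """A tiny planted instance for fast training-path tests."""
    model = cg.PlantedModel(n_circ=16, n_dis=8, n_blocks=2, p_in=0.9, p_out=0.05, seed=5)
    y = cg.generate_associations(model)
    dag = cg.generate_ontology(model)
    sims = cg.compute_all_similarities(y, dag)
    return {"model": model, "Y": y, "dag": dag, "sims": sims}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_association(rng, nc, nd):
    """Random 0/1 matrix with at least one positive."""
    values = (rng.random((nc, nd)) < 0.4).astype(float)
    if values.sum() == 0:
        values[rng.integers(nc), rng.integers(nd)] = 1.0
    return cg.AssociationMatrix(
        values,
        [f"c{i}" for i in range(nc)],
        [f"d{j}" for j in range(nd)],
    )


def random_symmetric_unit(rng, n):
    """Random symmetric matrix with unit diagonal, entries in [0, 1]."""
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a
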