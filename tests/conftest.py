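import numpy as np
import pytest

from fluorosite import (FixtureSpec, build_parameter_table,
                        generate_label_database, generate_toy_structure,
                        synthetic_conservation, train_parameter_scores)


@pytest.fixture(scope="session")
def helix():
    return generate_toy_structure(FixtureSpec("helix", 12))


@pytest.fixture(scope="session")
def globule():
    return generate_toy_structure(FixtureSpec("globule", 110, seed=1))


@pytest.fixture(scope="session")
def globule_table(globule):
    """Full 28-parameter table with synthetic conservation annotation."""
    return build_parameter_table(
        globule, annotations={"consurf": synthetic_conservation(globule, seed=5)})


@pytest.fixture(scope="session")
def null_database(globule_table):
    """Uniformly sampled labeled set (no planted enrichment)."""
    return generate_label_database(globule_table, None, n_labeled=40, seed=3)


@pytest.fixture(scope="session")
def null_model(globule_table, null_database):
    return train_parameter_scores(globule_table, null_database,
                                  parameter_ids=(11, 13, 18, 25),
                                  min_coverage=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
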