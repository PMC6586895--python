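import numpy as np
import pytest

import combosyn as cs


SMALL_CONFIG = dict(
    n_drugs=12,
    n_cell_lines=10,
    n_combos=20,
    n_genes=60,
    n_modules=3,
    n_proteins=15,
    n_pathways=6,
    n_domains=12,
    coverage=0.5,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-experiment cohort small enough for per-test featurization."""
    return cs.generate_cohort(cs.SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return cs.featurize_cohort(small_cohort, cs.FeaturizeConfig(n_modules=3))


@pytest.fixture(scope="session")
def small_y(small_cohort):
    return np.array([e.synergy for e in small_cohort.experiments])


@pytest.fixture()
def toy_network():
    """The worked toy graph: edges A-B, A-C, B-C, C-D."""
    return cs.SynergyNetwork(edges=[("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")])
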