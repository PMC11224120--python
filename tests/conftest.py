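import numpy as np
import pytest

from frustnet.synthetic import CohortConfig, generate_cohort, make_planted_partitions


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small three-condition resting cohort with a planted reconfiguration
    (25% of nodes reassigned in the third condition), shared across tests."""
    conditions = ("pre-RS", "rest-ctrl", "post-RS")
    parts = make_planted_partitions(30, conditions, n_modules=3,
                                    reassign_fractions={"rest-ctrl": 0.0,
                                                        "post-RS": 0.25},
                                    seed=7)
    cfg = CohortConfig(n_subjects=6, n_nodes=30, conditions=conditions,
                       n_volumes_rest=250, planted_partitions=parts,
                       phenotype_effects={}, seed=7)
    series, phenotypes, ground_truth = generate_cohort(cfg)
    return cfg, series, phenotypes, ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
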