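import numpy as np
import pandas as pd
import pytest

import dearisk as d
from dearisk.dea import DMURecord, DMUSet


def random_dmuset(rng: np.random.Generator, n: int, m: int = 2,
                  s: int = 1) -> DMUSet:
    """Random strictly positive DMU instance for property tests."""
    X = rng.uniform(0.5, 10.0, size=(n, m))
    Y = rng.uniform(0.5, 10.0, size=(n, s))
    return DMUSet(
        DMURecord(f"d{i}", tuple(X[i]), tuple(Y[i])) for i in range(n)
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """One moderately sized simulated cohort shared across tests."""
    cfg = d.SimConfig(n_subjects=400, seed=42)
    cohort, genotypes, weights, truth = d.simulate_cohort(cfg)
    cohort = d.simulate_followup(cohort, cfg)
    return cohort, genotypes, weights, truth


@pytest.fixture(scope="session")
def scored_cohort(sim_cohort):
    """The same cohort with DEA efficiency scores attached."""
    cohort, _, _, truth = sim_cohort
    cohort = cohort.copy()
    scores = d.efficiency_scores(d.build_dea_frame(cohort))
    cohort["efficiency"] = cohort["subject_id"].map(scores)
    return cohort, truth
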