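"""Shared fixtures: schemas, synthetic tables and short reference fits.

Sampler fixtures use deliberately short schedules so the whole suite stays
fast; every stochastic fixture is seeded.
"""

import math

import numpy as np
import pytest

from paleoherd.data import AgeClassSchema, KillOffProfile, legge_schema
from paleoherd.mortality import MortalityModel
from paleoherd.sexratio import SexRatioGLMM
from paleoherd.simulate import generate_modern_synthetic

TRUE_BETA = (-0.02, -0.3, -0.01)
TRUE_OMEGA = 0.2
N_HERDS = 15
POPULATION = 500


@pytest.fixture(scope="session")
def legge():
    return legge_schema()


@pytest.fixture(scope="session")
def schema3():
    return AgeClassSchema.from_bounds([("J", 0, 12), ("S", 12, 36), ("A", 36, None)], terminal_cap=120)


@pytest.fixture(scope="session")
def modern_table(legge):
    return generate_modern_synthetic(
        TRUE_BETA, TRUE_OMEGA, N_HERDS, legge, POPULATION, seed=0, baseline=math.log(0.5)
    )


@pytest.fixture(scope="session")
def modern_posterior(modern_table):
    model = SexRatioGLMM(iterations=2000, burnin=500, thin=3, chains=2, random_state=0)
    model.fit(modern_table)
    return model.posterior_


@pytest.fixture(scope="session")
def theta_truth():
    return np.array([0.25, 0.15, 0.12, 0.10, 0.08, 0.08, 0.08, 0.07, 0.07])


@pytest.fixture(scope="session")
def profile200(legge, theta_truth):
    counts = np.random.default_rng(0).multinomial(200, theta_truth)
    return KillOffProfile("sim200", legge, counts.astype(np.int64))


@pytest.fixture(scope="session")
def ancient_fit(profile200, modern_posterior):
    model = MortalityModel(iterations=6000, burnin=1000, thin=5, chains=2, random_state=0)
    model.fit(profile200, modern=modern_posterior)
    return model
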