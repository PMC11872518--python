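import numpy as np
import pytest

from palbopk import (
    CohortConfig,
    DoseEvent,
    PopulationParameters,
    apply_allometry,
    default_population_parameters,
)

np.seterr(over="ignore", invalid="ignore")


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    return default_population_parameters()


@pytest.fixture(scope="session")
def pop_one_eta() -> PopulationParameters:
    """One random effect (on clearance) for quadrature-oracle comparisons."""
    return PopulationParameters(
        cl_pop=62.6, v1_pop=2370.0, v2_pop=682.0, q_pop=48.0, ka=0.5,
        tlag=1.0, omega=np.array([[0.09]]), omega_names=("cl",),
        sigma_prop=0.2)


@pytest.fixture(scope="session")
def typical_individual(pop):
    return apply_allometry(pop, 70.0)


@pytest.fixture(scope="session")
def daily_doses():
    """21 daily 125 mg doses (one treatment cycle's dosing block)."""
    return [DoseEvent(time=24.0 * i, amount=125.0) for i in range(21)]


def random_individual(rng):
    """A random positive-parameter individual on plausible scales."""
    from palbopk import individual_from_eta

    pop = PopulationParameters(
        cl_pop=float(rng.uniform(20, 120)),
        v1_pop=float(rng.uniform(500, 4000)),
        v2_pop=float(rng.uniform(100, 1500)),
        q_pop=float(rng.uniform(10, 100)),
        ka=float(rng.uniform(0.2, 2.0)),
        tlag=float(rng.uniform(0.0, 2.0)),
        omega=0.09 * np.eye(2),
        sigma_prop=0.2,
        wt_ref=70.0,
    )
    weight = float(rng.uniform(45, 120))
    eta = rng.normal(0.0, 0.3, size=2)
    return individual_from_eta(pop, weight, eta)


@pytest.fixture(scope="session")
def small_sparse_cohort(pop):
    from palbopk import generate_cohort

    return generate_cohort(CohortConfig(n_patients=40, pop=pop, seed=7))
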