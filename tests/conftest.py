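import numpy as np
import pytest

from actinex import (
    ATTO488_CAL,
    KineticFitProblem,
    REFERENCE_RATES,
    generate_association_bundle,
    generate_chase,
    global_kinetic_fit,
)


@pytest.fixture(scope="session")
def rates():
    return REFERENCE_RATES


@pytest.fixture(scope="session")
def cal():
    return ATTO488_CAL


@pytest.fixture(scope="session")
def noiseless_bundle(rates):
    """Four association traces (25-200 nM analog, 2 µM actin, 10-s sampling)
    plus one 100-µM-ATP chase, all noiseless."""
    assoc = generate_association_bundle(rates)
    chase = generate_chase(rates)
    return assoc + [chase]


@pytest.fixture(scope="session")
def full_problem(noiseless_bundle, cal):
    return KineticFitProblem(
        datasets=list(noiseless_bundle),
        calibrations=[cal] * len(noiseless_bundle),
        k_on_T=10.0,
    )


@pytest.fixture(scope="session")
def full_fit(full_problem):
    """Global fit of the full noiseless bundle (shared: it takes seconds)."""
    return global_kinetic_fit(full_problem)


def reduced_problem(noise=None, seed=None):
    """Small bundle (two association traces + chase, 20-s sampling) for tests
    that need many refits."""
    from actinex import NoiseModel

    nm = NoiseModel(sd=0.0) if noise is None else NoiseModel(sd=noise, seed=seed)
    assoc = generate_association_bundle(
        REFERENCE_RATES, S_totals=(0.05, 0.2), dt=20.0, noise=nm
    )
    chase = generate_chase(REFERENCE_RATES, dt=20.0, noise=nm)
    return KineticFitProblem(
        datasets=assoc + [chase],
        calibrations=[ATTO488_CAL] * 3,
        k_on_T=10.0,
    )


@pytest.fixture(scope="session")
def small_problem():
    return reduced_problem()
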