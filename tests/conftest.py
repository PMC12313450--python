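import numpy as np
import pytest

from neopkpd import (
    DoseEvent,
    DoseSchedule,
    IndividualParameters,
    load_growth_reference,
    load_model_spec,
    load_regimen_catalog,
)


@pytest.fixture(scope="session")
def demo_spec():
    return load_model_spec("demo")


@pytest.fixture(scope="session")
def amox_spec():
    return load_model_spec("amoxicillin")


@pytest.fixture(scope="session")
def benzyl_spec():
    return load_model_spec("benzylpenicillin")


@pytest.fixture(scope="session")
def growth_ref():
    return load_growth_reference()


@pytest.fixture(scope="session")
def catalog():
    return load_regimen_catalog()


def random_params(rng: np.random.Generator, two_cpt: bool = False) -> IndividualParameters:
    """Random but physiologic parameter set (CL 0.02-1 L/h, V 0.2-3 L)."""
    cl = float(np.exp(rng.uniform(np.log(0.02), np.log(1.0))))
    v = float(np.exp(rng.uniform(np.log(0.2), np.log(3.0))))
    if not two_cpt:
        return IndividualParameters("r", cl=cl, v=v)
    q = float(np.exp(rng.uniform(np.log(0.01), np.log(0.5))))
    v2 = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
    return IndividualParameters("r", cl=cl, v=v, q=q, v2=v2)


def random_schedule(rng: np.random.Generator, window: float = 48.0) -> DoseSchedule:
    """1-8 infusions with random start times, amounts and durations."""
    n = int(rng.integers(1, 9))
    events = [
        DoseEvent(
            start_time=float(rng.uniform(0, 0.8 * window)),
            amount=float(rng.uniform(5, 100)),
            duration=float(rng.uniform(5 / 60, 4.0)),
        )
        for _ in range(n)
    ]
    return DoseSchedule("r", events)
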