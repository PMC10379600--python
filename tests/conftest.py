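import numpy as np
import pytest

from cmcgame import GameState, baseline_parameters, validate_parameters

#: Baseline constants of the two-subject game, frozen for fidelity checks.
BASELINE_TWO = {
    "I": 26.0, "U": 5.0, "Sl": 14.0, "Tp": 12.0, "R": 3.0, "Sp": 2.0,
    "D": 25.0, "v": 0.5, "pi": 0.5, "eps": 0.5, "xi": 0.5,
}

#: Tripartite extension of the baseline.
BASELINE_THREE = {**BASELINE_TWO, "Tg": 6.0, "F": 6.0, "A": 10.0, "phi": 0.5}


@pytest.fixture(scope="session")
def params_two():
    return baseline_parameters("two")


@pytest.fixture(scope="session")
def params_three():
    return baseline_parameters("three")


@pytest.fixture
def interior_two():
    return GameState(0.5, 0.5)


@pytest.fixture
def interior_three():
    return GameState(0.5, 0.5, 0.5)


def random_parameters(rng: np.random.Generator, model: str = "two"):
    """A random valid parameter set (costs/benefits in (0.5, 30],
    coefficients in [0, 1])."""
    raw = {
        key: float(rng.uniform(0.5, 30.0))
        for key in ("I", "U", "Sl", "Tp", "R", "Sp", "D")
    }
    for key in ("v", "pi", "eps", "xi"):
        raw[key] = float(rng.uniform(0.0, 1.0))
    if model == "three":
        for key in ("Tg", "F", "A"):
            raw[key] = float(rng.uniform(0.5, 30.0))
        raw["phi"] = float(rng.uniform(0.0, 1.0))
    return validate_parameters(raw, model=model)
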