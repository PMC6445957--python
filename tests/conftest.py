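import numpy as np
import pytest

from angiosprout.modelio import ModelDescription, ReactionDef, SpeciesDef, packaged_model
from angiosprout.signaling import SignalingModel


@pytest.fixture(scope="session")
def model_description():
    return packaged_model()


@pytest.fixture(scope="session")
def model(model_description):
    return SignalingModel(model_description)


def toy_decay_model(k: float = 0.01) -> ModelDescription:
    """One species, pure first-order decay: x' = -k x."""
    return ModelDescription(
        name="decay",
        species=[SpeciesDef("x", 100.0), SpeciesDef("sink", 0.0, boundary=True)],
        parameters={"k": k},
        reactions=[ReactionDef(id="deg", kind="mass_action", k="k",
                               rate_species=("x",), consume=("x",), produce=("sink",))],
    )


def toy_birth_death_model() -> ModelDescription:
    """Two coupled species with production, conversion, and decay.

    Gentle rates so the sub-step criterion stays inactive at the step sizes
    used in the convergence study.
    """
    return ModelDescription(
        name="birth_death",
        species=[
            SpeciesDef("a", 40.0), SpeciesDef("b", 5.0),
            SpeciesDef("source", 0.0, boundary=True),
            SpeciesDef("sink", 0.0, boundary=True),
        ],
        parameters={"v_in": 4.0, "k_ab": 0.05, "k_a": 0.08, "k_b": 0.12},
        reactions=[
            ReactionDef(id="birth", kind="mass_action", k="v_in",
                        rate_species=("source",), consume=(), produce=("a",)),
            ReactionDef(id="conv", kind="mass_action", k="k_ab",
                        rate_species=("a",), consume=("a",), produce=("b",)),
            ReactionDef(id="deg_a", kind="mass_action", k="k_a",
                        rate_species=("a",), consume=("a",), produce=("sink",)),
            ReactionDef(id="deg_b", kind="mass_action", k="k_b",
                        rate_species=("b",), consume=("b",), produce=("sink",)),
        ],
    )


# "source" is a boundary species used as a constant-1 rate factor
@pytest.fixture()
def birth_death():
    return SignalingModel(toy_birth_death_model())


@pytest.fixture()
def decay():
    return SignalingModel(toy_decay_model())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
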