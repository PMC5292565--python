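import numpy as np
import pytest

from vegfnet import (CompiledModel, MoleculeType, packaged_model)


@pytest.fixture(scope="session")
def model():
    """The packaged VEGF-TSP1 model definition."""
    return packaged_model()


@pytest.fixture(scope="session")
def network(model):
    return model.generate()


@pytest.fixture(scope="session")
def compiled(model, network):
    """Compiled full model; the equilibration cache is shared session-wide."""
    return CompiledModel(model, network)


@pytest.fixture(scope="session")
def toy_types():
    return {"L": MoleculeType("L", ("r",)),
            "R": MoleculeType("R", ("l",))}


TOY_MODEL_TEXT = """
begin parameters
  kon  2.0
  koff 0.5
  L0   10
  R0   20
end parameters
begin molecule types
  L(r)
  R(l)
end molecule types
begin seed species
  L(r)@surf  L0
  R(l)@surf  R0
end seed species
begin observables
  Molecules bound L(r!+)
end observables
begin reaction rules
  bind: L(r) + R(l) <-> L(r!1).R(l!1)  kon, koff
end reaction rules
"""


@pytest.fixture(scope="session")
def toy_model_text():
    return TOY_MODEL_TEXT


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
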