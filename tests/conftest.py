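import pytest

from boolscan.expr import Var
from boolscan.fixtures import toy_macrophage_fixture
from boolscan.model import BooleanModel, Node


@pytest.fixture(scope="session")
def toy():
    return toy_macrophage_fixture()


@pytest.fixture()
def two_node_loop():
    """A = NOT B, B = A: a single 4-cycle, no fixed point."""
    return BooleanModel(nodes=(Node("A"), Node("B")),
                        rules={"A": ~Var("B"), "B": Var("A")},
                        name="loop2")


@pytest.fixture()
def chain_model():
    """I -> A -> P plus a disconnected input J."""
    return BooleanModel(
        nodes=(Node("I", kind="input"), Node("A"), Node("P"),
               Node("J", kind="input")),
        rules={"A": Var("I"), "P": Var("A")},
        name="chain")
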