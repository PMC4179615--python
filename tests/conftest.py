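import numpy as np
import pytest

from branchcov.models import make_nr_model, read_paml_model


@pytest.fixture(scope="session")
def nr4():
    return make_nr_model(4)


@pytest.fixture(scope="session")
def nr20():
    return make_nr_model(20)


@pytest.fixture(scope="session")
def general_model(tmp_path_factory):
    """A reversible 4-state model with unequal rates and frequencies.

    Exercises the numerical (non-closed-form) code paths; written and read
    through the PAML dialect so the construction matches user input.
    """
    path = tmp_path_factory.mktemp("models") / "toy.paml"
    path.write_text("2.0\n1.0 3.0\n0.5 1.5 2.5\n\n0.3 0.2 0.3 0.2\n")
    return read_paml_model(path, 4, name="toy-gtr")


@pytest.fixture
def rng():
    return np.random.default_rng(20140925)
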