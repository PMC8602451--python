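import numpy as np
import pytest

from simenrich import ProteinRecord, Proteome
from simenrich.simulate import ProteomeModel, generate_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def tiny_proteome():
    """Five handcrafted proteins with known SIM content."""
    return Proteome([
        ProteinRecord("P00001", "LLALAAAAAAAAAAAAAAAA", name="SIM1_TEST"),
        ProteinRecord("P00002", "A" * 20, name="NOSIM_TEST"),
        ProteinRecord("P00003", "LIVLAAAAAAAALLALAAAA", name="SIM2_TEST"),
        ProteinRecord("P00004", "DDDDLLALAAAA", name="FLANK_TEST"),
        ProteinRecord("P00005", "M" + "A" * 99, name="LONG_TEST"),
    ], source_label="tiny")


@pytest.fixture(scope="session")
def synthetic_proteome():
    """A 300-protein human-composition proteome with incidental SIMs."""
    proteome, _ = generate_proteome(
        ProteomeModel(n_proteins=300, length_median=200, seed=11))
    return proteome


def random_sequence(rng, length, alphabet=AA):
    return "".join(rng.choice(list(alphabet), size=length))
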