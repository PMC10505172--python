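import numpy as np
import pytest

from phagescan import library_design as ld
from phagescan import synthgen as sg

HD2 = "EEDDYTAYAPLTCYFT"
HD2SCR = "TLETDTFYECPDAYAY"
EV4_PEPTIDE = "EEEDDYTAYAPLTAYFTN"  # Ev4 Glu14-Asn31 octadecapeptide


@pytest.fixture(scope="session")
def hd2_tile() -> ld.PeptideVariant:
    """HD2 as a wild-type tile of a synthetic 24-mer parent."""
    parent = ld.ProteinRecord("SYN24", "A" * 8 + HD2)
    return ld.tile_peptides(parent)[8]


@pytest.fixture(scope="session")
def small_study():
    """A small seeded synthetic selection study shared across tests."""
    parents, truth = sg.make_parents(n=2, seed=11, chemokines=("CK1", "CK2"))
    library = ld.build_library(parents)
    sg.assign_affinities(library, truth, seed=11)
    input_table, outputs = sg.simulate_experiment(library, truth, depth=50_000, seed=11)
    return parents, truth, library, input_table, outputs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
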