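"""Shared fixtures: toy structures and models, built once per session."""

import numpy as np
import pytest

from swapfold.go_model import build_go_model, build_tandem_model
from swapfold.structures import ToySpec, make_toy_structure


@pytest.fixture(scope="session")
def hairpin():
    """Two-strand hairpin toy: 15 residues, one cuttable loop."""
    return make_toy_structure(ToySpec(
        n_strands=2, strand_length=6, loop_length=3, termini_gap=0.48, seed=1,
    ))


@pytest.fixture(scope="session")
def hairpin_domain(hairpin):
    return build_go_model(hairpin, energy_unit=1.0)


@pytest.fixture(scope="session")
def hairpin_tandem(hairpin_domain):
    """Tandem dimer of the hairpin with a 3-residue GSG linker (L = 18)."""
    return build_tandem_model(hairpin_domain, "GSG")


@pytest.fixture(scope="session")
def meander():
    """Four-strand meander with long loops: three auto-detectable cut sites."""
    return make_toy_structure(ToySpec(
        n_strands=4, strand_length=6, loop_length=7, termini_gap=1.4, seed=1,
    ))


@pytest.fixture(scope="session")
def meander_domain(meander):
    return build_go_model(meander, energy_unit=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
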