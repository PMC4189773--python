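import numpy as np
import pytest

from carbscan import (
    AtomSelection,
    FixtureSpec,
    load_default_forcefield,
    make_toy_complex,
)
from carbscan.model import Atom, Residue, Structure


@pytest.fixture(scope="session")
def ff():
    return load_default_forcefield()


@pytest.fixture(scope="session")
def ligand_sel():
    return AtomSelection.make(residue_names=["LIG"])


@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    """One shared deterministic toy complex with ground truth."""
    out = tmp_path_factory.mktemp("toy")
    return make_toy_complex(FixtureSpec(seed=2), out_dir=str(out))


def make_structure(*residues: Residue) -> Structure:
    return Structure(residues=list(residues))


def simple_residue(name, chain, number, atoms):
    """Residue from (atom_name, element, xyz) triples."""
    return Residue(
        chain_id=chain,
        number=number,
        name=name,
        atoms=[Atom(name=an, element=el, position=np.asarray(p, float))
               for an, el, p in atoms],
    )
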