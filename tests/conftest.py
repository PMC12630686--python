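import numpy as np
import pytest

from glueprint.structure_io import Atom, StructureModel, assign_radii
from glueprint.synth import make_toy_complex


def pseudo_atom(serial, chain, pos, radius=1.7, name=None, residue_name="SPH",
                residue_seq=1, is_ligand=False, element="C"):
    return Atom(serial=serial, name=name or f"C{serial}", element=element,
                residue_name=residue_name, residue_seq=residue_seq,
                chain_id=chain, position=np.asarray(pos, dtype=float),
                radius=radius, is_ligand=is_ligand)


@pytest.fixture
def single_atom_model():
    m = StructureModel(atoms=[pseudo_atom(1, "A", [0.0, 0.0, 0.0])])
    return assign_radii(m)


@pytest.fixture
def two_atom_model():
    m = StructureModel(atoms=[pseudo_atom(1, "A", [0.0, 0.0, 0.0]),
                              pseudo_atom(2, "B", [2.0, 0.0, 0.0])])
    return assign_radii(m)


@pytest.fixture(scope="session")
def toy_dimer():
    """Mirror-symmetric bridged toy complex (seed fixed for the suite)."""
    return make_toy_complex(n_per_subunit=50, gap=1.0,
                            ligand_at_interface=True, seed=7)


@pytest.fixture(scope="session")
def toy_dimer_apart():
    return make_toy_complex(n_per_subunit=50, gap=30.0,
                            ligand_at_interface=False, seed=7)
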