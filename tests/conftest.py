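import numpy as np
import pytest

import porenm as pn


@pytest.fixture(scope="session")
def hexamer_spec():
    return pn.OligomerSpec()


@pytest.fixture(scope="session")
def hexamer(hexamer_spec):
    return pn.make_cn_oligomer(hexamer_spec)


@pytest.fixture(scope="session")
def hexamer_bridge(hexamer_spec):
    donor, acceptor = pn.bridge_residues(hexamer_spec)
    return pn.BridgeSpec(donor=(donor, "LYS"), acceptor=(acceptor, "ARG"))


@pytest.fixture(scope="session")
def hexamer_networks(hexamer, hexamer_bridge):
    unbound = pn.build_spring_network(hexamer)
    bound = pn.add_bridge_springs(unbound, hexamer, hexamer_bridge)
    return unbound, bound


@pytest.fixture(scope="session")
def hexamer_modes(hexamer_networks):
    unbound, bound = hexamer_networks
    return (
        pn.compute_modes(pn.build_hessian(unbound)),
        pn.compute_modes(pn.build_hessian(bound)),
    )


def make_full_atom(records, label="synthetic"):
    """Build a FullAtomStructure from (chain, res_id, res_name, atom, xyz) tuples."""
    return pn.FullAtomStructure(
        chain_ids=np.array([r[0] for r in records]),
        res_ids=np.array([r[1] for r in records]),
        res_names=np.array([r[2] for r in records]),
        atom_names=np.array([r[3] for r in records]),
        ins_codes=np.array(["" for _ in records]),
        coords=np.array([r[4] for r in records], dtype=float),
        source_label=label,
    )


@pytest.fixture
def full_atom_factory():
    return make_full_atom


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       6.250   2.000   3.000  1.00  0.00           C
HETATM    4  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER B   1       0.000   5.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   9.000  1.00  0.00           C
ATOM      3  CA  SER B   1       0.000   5.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path
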