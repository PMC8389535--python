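import numpy as np
import pytest

from pocketdrug.fixtures import PocketSpec, make_labeled_table, synthetic_pocket
from pocketdrug.structio import Atom, Pocket, Residue, ResidueClass


THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  P     A B   5      10.000   0.000   0.000  1.00  0.00           P
ATOM      6  O5'   A B   5      11.000   1.000   0.000  1.00  0.00           O
ATOM      7  C1'   A B   5      12.500   0.500   1.000  1.00  0.00           C
ATOM      8  N9    A B   5      13.500   1.200   1.800  1.00  0.00           N
HETATM    9  C1  LIG A 101       5.000   5.000   5.000  1.00  0.00           C
HETATM   10  C2  LIG A 101       6.200   5.600   5.000  1.00  0.00           C
HETATM   11  O1  LIG A 101       7.000   4.700   5.400  1.00  0.00           O
END
"""

THREE_RESIDUE_CIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM   1  N N     . GLY A 1 1 ?  0.000 0.000 0.000 1.00 0.00 1   A 1
ATOM   2  C CA    . GLY A 1 1 ?  1.458 0.000 0.000 1.00 0.00 1   A 1
ATOM   3  C C     . GLY A 1 1 ?  2.009 1.420 0.000 1.00 0.00 1   A 1
ATOM   4  O O     . GLY A 1 1 ?  1.251 2.390 0.000 1.00 0.00 1   A 1
ATOM   5  P P     . A   B 2 1 ? 10.000 0.000 0.000 1.00 0.00 5   B 1
ATOM   6  O "O5'" . A   B 2 1 ? 11.000 1.000 0.000 1.00 0.00 5   B 1
ATOM   7  C "C1'" . A   B 2 1 ? 12.500 0.500 1.000 1.00 0.00 5   B 1
ATOM   8  N N9    . A   B 2 1 ? 13.500 1.200 1.800 1.00 0.00 5   B 1
HETATM 9  C C1    . LIG C 3 . ?  5.000 5.000 5.000 1.00 0.00 101 A 1
HETATM 10 C C2    . LIG C 3 . ?  6.200 5.600 5.000 1.00 0.00 101 A 1
HETATM 11 O O1    . LIG C 3 . ?  7.000 4.700 5.400 1.00 0.00 101 A 1
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def three_residue_cif(tmp_path):
    path = tmp_path / "three.cif"
    path.write_text(THREE_RESIDUE_CIF)
    return path


def make_residue(name, chain, seq, residue_class, atoms, parent=None):
    """Build a residue from (atom_name, element, xyz) triples."""
    res = Residue(name=name, chain_id=chain, seq_id=seq,
                  residue_class=residue_class, parent_code=parent)
    for atom_name, element, pos in atoms:
        res.atoms.append(Atom(element=element, position=np.asarray(pos, float),
                              name=atom_name, residue=res))
    return res


def make_point_pocket(wall_positions, ligand_positions, wall_element="C",
                      pocket_id="test"):
    """Pocket of single-atom glycine pseudo-residues around a carbon ligand."""
    receptor = []
    for i, pos in enumerate(wall_positions):
        name = "CA" if wall_element == "C" else "O"
        res = make_residue("GLY", "W", i + 1, ResidueClass.AMINO_ACID,
                           [(name, wall_element, pos)])
        receptor.extend(res.atoms)
    lig = make_residue("LIG", "L", 1, ResidueClass.LIGAND,
                       [(f"C{j+1}", "C", p) for j, p in enumerate(ligand_positions)])
    return Pocket(pocket_id=pocket_id, receptor_atoms=receptor, ligand=lig)


@pytest.fixture
def cylinder_pocket():
    return synthetic_pocket(PocketSpec(geometry="deep_cylinder",
                                       n_wall_atoms=60, seed=1))


@pytest.fixture
def labeled_table():
    return make_labeled_table(n=200, effect=1.0, noise_sd=0.1, seed=11)
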