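"""Characterize a ligand: QED drug-likeness and ligand efficiency.

Builds linezolid (an oxazolidinone antibiotic that binds the 50S ribosomal
subunit) from SMILES and prints its drug-likeness and binding efficiency.
"""

from rdkit import Chem

from pocketdrug import compute_qed, ligand_efficiency, physchem_profile, qed_class

LINEZOLID = "CC(=O)NC[C@H]1CN(c2ccc(N3CCOCC3)c(F)c2)C(=O)O1"

mol = Chem.MolFromSmiles(LINEZOLID)
qed = compute_qed(mol)
# Kd = 20,000 nM against the bacterial ribosome
le = ligand_efficiency(kd=20_000e-9, n_heavy=mol.GetNumHeavyAtoms())

print(f"linezolid: QED = {qed:.2f} ({qed_class(qed)})")
print(f"ligand efficiency = {le:.2f} kcal/mol per heavy atom")
print(f"physchem: {physchem_profile(mol)}")
# QED >= 0.67 means the ligand is drug-like; LE around 0.3 kcal/mol/atom is
# the conventional hit-to-lead efficiency bar, so 0.27 is just below it.
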