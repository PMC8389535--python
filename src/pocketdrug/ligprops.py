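"""Ligand characterization: QED drug-likeness, ligand efficiency, physchem.

QED (quantitative estimate of drug-likeness) is computed with RDKit using
average descriptor weights, and classed drug-like (≥ 0.67), moderate, or
less drug-like (≤ 0.49).  Ligand efficiency is the binding free energy per
heavy atom, LE = −RT·ln(Kd)/N_heavy in kcal·mol⁻¹·heavy-atom⁻¹ at 298.15 K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

logger = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.987e-3        # kcal·mol⁻¹·K⁻¹
STANDARD_TEMPERATURE = 298.15       # K
QED_DRUG_LIKE = 0.67
QED_LESS_DRUG_LIKE = 0.49

DRUG_LIKE = "drug_like"
MODERATE = "moderate"
LESS_DRUG_LIKE = "less_drug_like"


def qed_class(qed: float) -> str:
    """Drug-likeness class from a QED score: ≥ 0.67 drug-like, ≤ 0.49 less
    drug-like, in between moderate (both boundaries inclusive)."""
    if not 0.0 <= qed <= 1.0:
        raise ValueError(f"QED score {qed} outside [0, 1]")
    if qed >= QED_DRUG_LIKE:
        return DRUG_LIKE
    if qed <= QED_LESS_DRUG_LIKE:
        return LESS_DRUG_LIKE
    return MODERATE


def _as_mol(molecule: "Chem.Mol | str") -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"unparsable molecule: {molecule!r}")
    return mol


def compute_qed(molecule: "Chem.Mol | str") -> float:
    """QED with average (mean) descriptor weights: the geometric mean of the
    eight property desirability functions."""
    mol = _as_mol(molecule)
    return float(QED.qed(mol, w=QED.WEIGHT_MEAN))


def ligand_efficiency(kd: float, n_heavy: int,
                      temperature: float = STANDARD_TEMPERATURE) -> float:
    """LE = −RT·ln(Kd)/N_heavy in kcal·mol⁻¹ per heavy atom (Kd in molar).

    A Kd at or above 1 M implies a non-negative binding free energy; the LE
    is then floored at 0 with a warning."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if n_heavy < 1:
        raise ValueError("heavy-atom count must be at least 1")
    le = -GAS_CONSTANT_KCAL * temperature * math.log(kd) / n_heavy
    if le < 0:
        logger.warning("Kd=%.3g M >= 1 M gives negative LE; floored at 0", kd)
        return 0.0
    return le


def physchem_profile(molecule: "Chem.Mol | str") -> dict:
    """Eight standard physicochemical properties: molecular weight, H-bond
    donors/acceptors, rotatable bonds, calculated logP, Fsp3, ring count and
    aromatic ring count."""
    mol = _as_mol(molecule)
    return {
        "MW": float(Descriptors.MolWt(mol)),
        "HBD": int(Lipinski.NumHDonors(mol)),
        "HBA": int(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": int(Lipinski.NumRotatableBonds(mol)),
        "clogP": float(Crippen.MolLogP(mol)),
        "Fsp3": float(rdMolDescriptors.CalcFractionCSP3(mol)),
        "rings": int(rdMolDescriptors.CalcNumRings(mol)),
        "aromatic_rings": int(rdMolDescriptors.CalcNumAromaticRings(mol)),
    }


@dataclass
class LigandRecord:
    ligand_id: str
    smiles: str
    qed: float
    qed_class: str
    physchem: dict
    kd: float | None = None          # molar
    le: float | None = None          # kcal/mol per heavy atom

    @classmethod
    def from_smiles(cls, ligand_id: str, smiles: str,
                    kd: float | None = None) -> "LigandRecord":
        mol = _as_mol(smiles)
        q = compute_qed(mol)
        le = None
        if kd is not None:
            le = ligand_efficiency(kd, mol.GetNumHeavyAtoms())
        return cls(ligand_id=ligand_id, smiles=smiles, qed=q,
                   qed_class=qed_class(q), physchem=physchem_profile(mol),
                   kd=kd, le=le)


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES list (one molecule per line: ``SMILES id``)."""
    entries = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        lig_id = parts[1] if len(parts) > 1 else f"lig{i}"
        entries.append((lig_id, smiles))
    return entries
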