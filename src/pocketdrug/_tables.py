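"""Chemical reference tables: residue classes, radii, polarity atom maps.

All tables are editable module-level constants so that users can extend them
(e.g. add a modified-nucleotide parent mapping or an additive to the dataset
exclusion list) without touching any algorithmic code.
"""

from __future__ import annotations

# --- residue classification ------------------------------------------------

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

STANDARD_NUCLEOTIDES = {
    "A", "C", "G", "U", "I",
    "DA", "DC", "DG", "DT", "DU", "DI",
}

#: modified nucleotide -> parent standard code (used for binding-site
#: sequence extraction and polarity typing).  Common PDB chemical-component
#: codes; extend as needed.
MODIFIED_NUCLEOTIDE_PARENTS = {
    "1MA": "A", "2MA": "A", "6MA": "A", "MA6": "A", "RIA": "A", "A2M": "A",
    "AET": "A", "12A": "A", "T6A": "A", "MIA": "A",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G",
    "G7M": "G", "QUO": "G", "YYG": "G", "O2G": "G",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "5IC": "C", "CCC": "C",
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "2MU": "U", "70U": "U", "S4U": "U", "DHU": "U", "3MU": "U",
    "5BU": "U", "UMS": "U",
}

#: monoatomic ions classified as metals
METAL_CODES = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "FE2",
    "CO", "NI", "CU", "CU1", "ZN", "CD", "HG", "AG", "AU", "TL", "PB", "AL",
    "GA", "IN", "YB", "LA", "CE", "SM", "EU", "GD", "TB", "LU", "W", "MO",
    "V", "CR", "PT", "PD", "IR", "OS", "RU", "RE", "3CO", "NI2", "MN3",
}

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}

#: default dataset-assembly exclusion list: detergents, buffer salts and
#: crystallization additives commonly seen bound in crystal structures.
DEFAULT_EXCLUSION_LIST = {
    "GOL", "EDO", "PEG", "PG4", "PGE", "1PE", "P6G", "2PE", "PE3", "PE4",
    "SO4", "PO4", "ACT", "ACY", "CIT", "FLC", "TLA", "TAR", "MLI", "FMT",
    "DMS", "EOH", "MOH", "IPA", "MPD", "BME", "DTT", "TRS", "EPE", "MES",
    "CAC", "IMD", "NO3", "BCT", "CO3", "AZI", "SCN", "BR", "CL", "IOD", "F",
    "NH4", "BOG", "LDA", "SDS", "LMT", "DAO", "HTG", "C8E", "OCT", "UNX",
    "SPM", "SPD", "PUT", "BTB", "PIN", "MRD", "PDO", "BU3", "DIO", "HED",
}

# --- ProtOr united-atom radii ----------------------------------------------
# United-atom van der Waals radii (hydrogens folded into their heavy atom),
# keyed by atom class.  Values in Angstrom.
PROTOR_RADII = {
    "C3H0": 1.61,   # trigonal carbon, no H (carbonyl, carboxyl, guanidinium)
    "C3H1": 1.76,   # aromatic CH
    "C4H1": 1.88,   # aliphatic CH
    "C4H2": 1.88,   # aliphatic CH2
    "C4H3": 1.88,   # aliphatic CH3
    "N3H0": 1.64,
    "N3H1": 1.64,
    "N3H2": 1.64,
    "N4H3": 1.64,
    "O1H0": 1.42,   # carbonyl / carboxylate / phosphate oxygen
    "O2H1": 1.46,   # hydroxyl oxygen
    "S2H0": 1.77,
    "S2H1": 1.77,
    "P4H0": 1.80,
}

#: simple per-element fallback radii
ELEMENT_RADII = {
    "C": 1.88, "N": 1.64, "O": 1.42, "S": 1.77, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "ZN": 1.39, "MN": 1.39,
    "FE": 1.39, "CO": 1.39, "NI": 1.39, "CU": 1.40,
}

#: fallback radius for unknown atom types
FALLBACK_RADIUS = 1.80

#: radius used for superligand points and blocking carbons (aliphatic carbon)
SUPERLIGAND_POINT_RADIUS = 1.88

# atom names that carry a hydroxyl hydrogen (O2H1 class)
_HYDROXYL_O_NAMES = {"OG", "OG1", "OH", "O2'", "O3'", "O5'", "O2*", "O3*", "O5*"}
# aromatic ring carbon names in amino acids and nucleobases
_AROMATIC_C_NAMES = {
    "CG", "CD1", "CD2", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2",  # aa rings
    "C2", "C4", "C5", "C6", "C8",  # nucleobase rings
}
_AROMATIC_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}
# trigonal sp2 carbons without hydrogens
_TRIGONAL_C = {("ASP", "CG"), ("ASN", "CG"), ("GLU", "CD"), ("GLN", "CD"),
               ("ARG", "CZ"), ("TYR", "CZ")}


def protor_radius(element: str, residue_name: str | None = None,
                  atom_name: str | None = None) -> float:
    """United-atom radius for a heavy atom; ``FALLBACK_RADIUS`` if unknown.

    The class assignment is name-based for the standard residues; for
    anything else it falls back to a per-element radius.
    """
    el = element.upper()
    name = (atom_name or "").upper()
    res = (residue_name or "").upper()
    if el == "C":
        if name == "C" or (res, name) in _TRIGONAL_C:
            return PROTOR_RADII["C3H0"]
        if res in _AROMATIC_RESIDUES and name in _AROMATIC_C_NAMES:
            return PROTOR_RADII["C3H1"]
        if res in STANDARD_NUCLEOTIDES or res in MODIFIED_NUCLEOTIDE_PARENTS:
            if name in {"C2", "C4", "C5", "C6", "C8"}:
                # base ring carbons: C4/C5/C6 of pyrimidines, C2/C8 of purines
                return PROTOR_RADII["C3H1"]
        return PROTOR_RADII["C4H1"]
    if el == "N":
        return PROTOR_RADII["N3H0"]
    if el == "O":
        return PROTOR_RADII["O2H1"] if name in _HYDROXYL_O_NAMES else PROTOR_RADII["O1H0"]
    if el == "S":
        return PROTOR_RADII["S2H0"]
    if el == "P":
        return PROTOR_RADII["P4H0"]
    return ELEMENT_RADII.get(el, FALLBACK_RADIUS)


# --- polarity typing --------------------------------------------------------

#: glycosidic base nitrogens (bound to the ribose): hydrophobic per the
#: polarity model (N9 of purines, N1 of pyrimidines)
GLYCOSIDIC_N = {
    "A": "N9", "G": "N9", "I": "N9",
    "C": "N1", "U": "N1", "T": "N1",
    "DA": "N9", "DG": "N9", "DC": "N1", "DT": "N1", "DU": "N1",
}

#: endocyclic aromatic nitrogens of the nucleobases (split class)
ENDOCYCLIC_AROMATIC_N = {
    "A": {"N1", "N3", "N7"},
    "G": {"N1", "N3", "N7"},
    "I": {"N1", "N3", "N7"},
    "C": {"N3"},
    "U": {"N3"},
    "T": {"N3"},
    "DA": {"N1", "N3", "N7"},
    "DG": {"N1", "N3", "N7"},
    "DC": {"N3"},
    "DT": {"N3"},
    "DU": {"N3"},
}

#: exocyclic oxygen and nitrogen atoms of the nucleobases (split class)
EXOCYCLIC_BASE_ON = {
    "A": {"N6"},
    "G": {"O6", "N2"},
    "I": {"O6"},
    "C": {"O2", "N4"},
    "U": {"O2", "O4"},
    "T": {"O2", "O4"},
    "DA": {"N6"},
    "DG": {"O6", "N2"},
    "DC": {"O2", "N4"},
    "DT": {"O2", "O4"},
    "DU": {"O2", "O4"},
}

#: endocyclic aromatic nitrogens of amino-acid side chains (split class)
AA_AROMATIC_N = {
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
}

#: ring-atom names used for least-squares plane fits in the blocking-carbon
#: SASA split, keyed by parent residue code
RING_ATOMS = {
    "A": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "G": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "I": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "DA": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "DG": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "DC": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "DT": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "DU": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

# --- one-letter codes for alignment ----------------------------------------

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


def one_letter_code(residue_code: str) -> str:
    """One-letter alphabet for alignment: nucleotides map to themselves,
    amino acids to their standard one-letter code, anything else to X."""
    code = residue_code.upper()
    if code in STANDARD_NUCLEOTIDES:
        return code[-1]  # A/C/G/U/T/I, dropping the deoxy prefix
    if code in MODIFIED_NUCLEOTIDE_PARENTS:
        return MODIFIED_NUCLEOTIDE_PARENTS[code][-1]
    return AA_THREE_TO_ONE.get(code, "X")
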