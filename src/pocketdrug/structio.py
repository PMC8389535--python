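"""Structure parsing, pocket carving, metal variants and dataset filters.

Structures are read with gemmi (mmCIF and PDB) into a deliberately small
in-memory model — :class:`Atom` / :class:`Residue` / :class:`Structure` —
that carries exactly what the downstream surface and descriptor machinery
needs: elements, coordinates, atom names and a residue classification
(amino acid, nucleotide, modified nucleotide, ligand, metal, water, other).

A :class:`Pocket` is the 15 Å shell of receptor residues around a chosen
ligand.  Waters and metals are stripped at carving time; qualifying metals
(within 5 Å of the ligand) are reintroduced one at a time as separate
pocket variants by :func:`metal_variants`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from ._tables import (
    DEFAULT_EXCLUSION_LIST,
    METAL_CODES,
    MODIFIED_NUCLEOTIDE_PARENTS,
    STANDARD_AMINO_ACIDS,
    STANDARD_NUCLEOTIDES,
    WATER_CODES,
)

logger = logging.getLogger(__name__)


class ResidueClass(str, Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    MODIFIED_NUCLEOTIDE = "modified_nucleotide"
    LIGAND = "ligand"
    METAL = "metal"
    WATER = "water"
    OTHER = "other"


@dataclass(eq=False)
class Atom:
    """A single atom; identity-hashable so atoms can live in sets."""

    element: str
    position: np.ndarray
    name: str
    is_hydrogen: bool = False
    residue: "Residue | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError("atom element must be non-empty")


@dataclass(eq=False)
class Residue:
    name: str
    chain_id: str
    seq_id: int
    residue_class: ResidueClass
    atoms: list[Atom] = field(default_factory=list)
    parent_code: str | None = None

    def __post_init__(self) -> None:
        if self.residue_class is ResidueClass.MODIFIED_NUCLEOTIDE and not self.parent_code:
            raise ValueError(f"modified nucleotide {self.name} lacks parent_code")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.name)


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    model_index: int = 0

    def find_residue(self, chain_id: str, seq_id: int, name: str) -> Residue | None:
        for res in self.residues:
            if res.key() == (chain_id, seq_id, name):
                return res
        return None

    def ligands(self) -> list[Residue]:
        return [r for r in self.residues if r.residue_class is ResidueClass.LIGAND]


@dataclass
class Pocket:
    """Carved binding-site shell around a reference ligand."""

    pocket_id: str
    receptor_atoms: list[Atom]
    ligand: Residue
    metal: Residue | None = None
    source_structure: str = ""

    @property
    def all_occluding_atoms(self) -> list[Atom]:
        """Receptor heavy atoms plus the metal ion (if present)."""
        atoms = list(self.receptor_atoms)
        if self.metal is not None:
            atoms.extend(self.metal.heavy_atoms)
        return atoms

    def receptor_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.receptor_atoms], dtype=float).reshape(-1, 3)


def classify_residue_code(code: str, is_hetero: bool, n_heavy: int) -> tuple[ResidueClass, str | None]:
    """Classify a chemical-component code using the built-in tables.

    Returns (class, parent_code); parent_code is set for modified
    nucleotides only.
    """
    code = code.strip().upper()
    if code in WATER_CODES:
        return ResidueClass.WATER, None
    if code in STANDARD_AMINO_ACIDS:
        return ResidueClass.AMINO_ACID, None
    if code in STANDARD_NUCLEOTIDES:
        return ResidueClass.NUCLEOTIDE, None
    if code in MODIFIED_NUCLEOTIDE_PARENTS:
        return ResidueClass.MODIFIED_NUCLEOTIDE, MODIFIED_NUCLEOTIDE_PARENTS[code]
    if code in METAL_CODES and n_heavy == 1:
        return ResidueClass.METAL, None
    if is_hetero:
        return ResidueClass.LIGAND, None
    logger.warning("unknown residue code %r classified as 'other'", code)
    return ResidueClass.OTHER, None


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the retained atoms
    kept = set(id(a) for a in best.values())
    return [a for a in res if id(a) in kept]


def parse_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read an mmCIF or PDB file into a :class:`Structure`.

    Only the first model is kept.  Alternate locations are resolved to the
    highest-occupancy copy (ties broken by file order).  Hydrogens are
    retained but flagged; every distance and surface computation downstream
    ignores them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or "").lower()
    try:
        if fmt == "pdb" or (not fmt and path.suffix.lower() in {".pdb", ".ent"}):
            st = gemmi.read_pdb(str(path))
        elif fmt in {"mmcif", "cif"} or (not fmt and path.suffix.lower() in {".cif", ".mmcif"}):
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            atoms_raw = _resolve_altlocs(gres)
            het = gres.het_flag == "H"
            n_heavy = sum(1 for a in atoms_raw if not a.is_hydrogen())
            cls, parent = classify_residue_code(gres.name, het, n_heavy)
            res = Residue(
                name=gres.name.strip().upper(),
                chain_id=chain.name,
                seq_id=gres.seqid.num,
                residue_class=cls,
                parent_code=parent,
            )
            for a in atoms_raw:
                res.atoms.append(
                    Atom(
                        element=a.element.name.upper(),
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        name=a.name,
                        is_hydrogen=a.is_hydrogen(),
                        residue=res,
                    )
                )
            if res.atoms:
                residues.append(res)
    _check_unique(residues, path)
    return Structure(id=st.name or path.stem, residues=residues, model_index=0)


def _check_unique(residues: Sequence[Residue], path: Path) -> None:
    seen: set[tuple[str, int, str]] = set()
    for r in residues:
        k = r.key()
        if k in seen:
            logger.warning("duplicate residue key %s in %s", k, path)
        seen.add(k)


def carve_pocket(
    structure: Structure,
    ligand_selector: tuple[str, int, str],
    shell: float = 15.0,
    pocket_id: str | None = None,
) -> Pocket:
    """Carve the binding-site shell: keep every residue having at least one
    heavy atom within ``shell`` Å (inclusive) of any ligand heavy atom.

    The reference ligand itself, waters and metals are excluded from the
    receptor atom set; metal-containing variants are produced separately by
    :func:`metal_variants`.
    """
    chain_id, seq_id, name = ligand_selector
    ligand = structure.find_residue(chain_id, seq_id, name)
    if ligand is None:
        raise LookupError(f"ligand {chain_id}:{seq_id}:{name} not found in {structure.id}")
    lig_pos = np.array([a.position for a in ligand.heavy_atoms])
    if lig_pos.size == 0:
        raise LookupError(f"ligand {name} has no heavy atoms")
    receptor_atoms: list[Atom] = []
    for res in structure.residues:
        if res is ligand:
            continue
        if res.residue_class in (ResidueClass.WATER, ResidueClass.METAL):
            continue
        heavy = res.heavy_atoms
        if not heavy:
            continue
        pos = np.array([a.position for a in heavy])
        if cdist(pos, lig_pos).min() <= shell:
            receptor_atoms.extend(heavy)
    return Pocket(
        pocket_id=pocket_id or f"{structure.id}_{chain_id}{seq_id}{name}",
        receptor_atoms=receptor_atoms,
        ligand=ligand,
        metal=None,
        source_structure=structure.id,
    )


def metal_variants(structure: Structure, pocket: Pocket, cutoff: float = 5.0) -> list[Pocket]:
    """One pocket copy per metal ion lying within ``cutoff`` Å (inclusive)
    of any ligand heavy atom, each copy containing exactly that metal."""
    lig_pos = np.array([a.position for a in pocket.ligand.heavy_atoms])
    variants: list[Pocket] = []
    for res in structure.residues:
        if res.residue_class is not ResidueClass.METAL:
            continue
        pos = np.array([a.position for a in res.heavy_atoms])
        if pos.size and cdist(pos, lig_pos).min() <= cutoff:
            variants.append(
                Pocket(
                    pocket_id=f"{pocket.pocket_id}_{res.chain_id}{res.seq_id}{res.name}",
                    receptor_atoms=list(pocket.receptor_atoms),
                    ligand=pocket.ligand,
                    metal=res,
                    source_structure=pocket.source_structure,
                )
            )
    return variants


def filter_dataset_entries(
    structures: Iterable[Structure],
    exclusion_list: set[str] | None = None,
) -> list[tuple[Structure, tuple[str, int, str]]]:
    """Dataset-assembly filter: drop structures whose ligands are all
    excluded additives; for duplicated ligand codes within a structure keep
    only the first instance in file order; one entry per retained ligand."""
    excl = DEFAULT_EXCLUSION_LIST if exclusion_list is None else exclusion_list
    entries: list[tuple[Structure, tuple[str, int, str]]] = []
    for st in structures:
        ligands = [r for r in st.ligands() if r.name not in excl]
        if not ligands:
            continue
        seen_codes: set[str] = set()
        for lig in ligands:
            if lig.name in seen_codes:
                continue
            seen_codes.add(lig.name)
            entries.append((st, lig.key()))
    return entries


# --- pocket PDB round-trip --------------------------------------------------

def _pdb_atom_line(record: str, serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.position
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.name:>3s} "
        f"{res.chain_id[:1]:1s}{res.seq_id:>4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pocket_pdb(pocket: Pocket, path: str | Path) -> None:
    """Write a carved pocket as PDB with original coordinates, chain ids and
    residue numbers.  The reference ligand (and metal, if any) are written
    as HETATM; a REMARK line records the ligand selector so the pocket can
    be read back unambiguously."""
    lig = pocket.ligand
    lines = [
        f"REMARK 900 POCKET {pocket.pocket_id}",
        f"REMARK 900 LIGAND {lig.chain_id}:{lig.seq_id}:{lig.name}",
    ]
    serial = 0
    written: list[tuple[Residue, Atom, str]] = []
    by_res: dict[int, Residue] = {}
    for atom in pocket.receptor_atoms:
        res = atom.residue
        record = "ATOM" if res and res.residue_class in (
            ResidueClass.AMINO_ACID, ResidueClass.NUCLEOTIDE,
            ResidueClass.MODIFIED_NUCLEOTIDE) else "HETATM"
        written.append((res, atom, record))
    for atom in lig.heavy_atoms:
        written.append((lig, atom, "HETATM"))
    if pocket.metal is not None:
        for atom in pocket.metal.heavy_atoms:
            written.append((pocket.metal, atom, "HETATM"))
    for res, atom, record in written:
        serial += 1
        lines.append(_pdb_atom_line(record, serial, atom, res))
        by_res[serial] = res
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pocket_pdb(path: str | Path) -> Pocket:
    """Read a pocket written by :func:`write_pocket_pdb` (or any PDB file
    with a ``REMARK 900 LIGAND chain:seq:name`` line, or exactly one ligand
    residue)."""
    path = Path(path)
    selector: tuple[str, int, str] | None = None
    pocket_id = path.stem
    for line in path.read_text().splitlines():
        if line.startswith("REMARK 900 LIGAND"):
            token = line.split()[-1]
            chain, seq, name = token.split(":")
            selector = (chain, int(seq), name)
        elif line.startswith("REMARK 900 POCKET"):
            pocket_id = line.split()[-1]
    structure = parse_structure(path, format="pdb")
    if selector is None:
        ligs = structure.ligands()
        if len(ligs) != 1:
            raise ValueError(
                f"{path}: no LIGAND remark and {len(ligs)} ligand residues; "
                "cannot identify the reference ligand"
            )
        selector = ligs[0].key()
    pocket = carve_pocket(structure, selector, shell=float("inf"), pocket_id=pocket_id)
    metals = [r for r in structure.residues if r.residue_class is ResidueClass.METAL]
    if metals:
        pocket.metal = metals[0]
    return pocket
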