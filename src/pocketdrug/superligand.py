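"""Superligand construction: the negative print of a binding pocket.

A superligand is built by merging heavy atoms of sterically docked probe
molecules: poses whose van-der-Waals score per heavy atom is at most −1.3
are kept, and only atoms confirmed by a second pose (an atom from a
*different* molecule closer than 1.2 Å) survive the merge, deduplicated so
that no two retained points are closer than 1.2 Å.  If nothing survives,
the crystallographic ligand's heavy atoms are used verbatim.

Poses can come from any external docking program (multi-molecule SDF or
concatenated PDB) or from the built-in rigid-body steric sampler, which
scores placements with a soft Lennard-Jones potential in which every
receptor atom is treated as an uncharged carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Pocket

# soft Lennard-Jones parameters: identical carbon parameters for every
# receptor atom (the steric-only docking convention)
LJ_EPSILON = 0.1        # kcal/mol
LJ_RMIN = 3.4           # Angstrom
LJ_CLASH_CAP = 10.0     # kcal/mol cap per atom pair
LJ_CUTOFF = 8.0         # Angstrom interaction cutoff

SCORE_RATIO_CUTOFF = -1.3
MERGE_RADIUS = 1.2


@dataclass
class Pose:
    """A docked probe molecule: heavy-atom coordinates plus a steric score
    (arbitrary energy units, lower = better)."""

    positions: np.ndarray          # (n_heavy, 3)
    elements: list[str]
    vdw_score: float
    source_id: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.vdw_score):
            raise ValueError(f"pose {self.source_id}: non-finite score")

    @property
    def n_heavy(self) -> int:
        return len(self.positions)

    @property
    def score_ratio(self) -> float:
        return self.vdw_score / self.n_heavy


@dataclass
class Superligand:
    """Merged point set representing the pocket's negative print; points are
    treated as carbon-like spheres by all downstream surface computations."""

    points: np.ndarray             # (n, 3)
    origin: str                    # "merged_poses" | "crystal_ligand"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.points)


def filter_poses(poses: Sequence[Pose], ratio_cutoff: float = SCORE_RATIO_CUTOFF) -> list[Pose]:
    """Keep poses whose score per heavy atom is ≤ ``ratio_cutoff``
    (boundary inclusive)."""
    kept = []
    for p in poses:
        if p.n_heavy < 1:
            raise ValueError(f"pose {p.source_id} has no heavy atoms")
        if p.score_ratio <= ratio_cutoff:
            kept.append(p)
    return kept


def merge_poses(poses: Sequence[Pose], merge_radius: float = MERGE_RADIUS) -> Superligand:
    """Merge pose atoms into a superligand point set.

    An atom survives only if at least one atom from a *different* pose lies
    strictly within ``merge_radius`` of it; mutually close atoms are then
    deduplicated by a greedy pass in deterministic order (poses sorted by
    ``source_id``, atoms in input order): an atom is kept unless it lies
    strictly within ``merge_radius`` of an already-kept atom.  The result
    therefore has all pairwise distances ≥ ``merge_radius``.
    """
    if not poses:
        raise ValueError("merge_poses requires at least one pose")
    ordered = sorted(poses, key=lambda p: p.source_id)
    coords = []
    pose_idx = []
    for i, p in enumerate(ordered):
        coords.append(p.positions)
        pose_idx.extend([i] * p.n_heavy)
    all_pos = np.vstack(coords)
    pose_idx = np.array(pose_idx)
    tree = cKDTree(all_pos)
    pairs = tree.query_pairs(merge_radius, output_type="ndarray")
    # strict inequality: drop exact-boundary pairs
    if len(pairs):
        d = np.linalg.norm(all_pos[pairs[:, 0]] - all_pos[pairs[:, 1]], axis=1)
        pairs = pairs[d < merge_radius]
    confirmed = np.zeros(len(all_pos), dtype=bool)
    for i, j in pairs:
        if pose_idx[i] != pose_idx[j]:
            confirmed[i] = True
            confirmed[j] = True
    kept: list[np.ndarray] = []
    for idx in np.flatnonzero(confirmed):
        p = all_pos[idx]
        if all(np.linalg.norm(p - q) >= merge_radius for q in kept):
            kept.append(p)
    points = np.array(kept).reshape(-1, 3)
    provenance = sorted({p.source_id for p in ordered})
    return Superligand(points=points, origin="merged_poses", provenance=provenance)


def build_superligand(
    pocket: Pocket,
    poses: Sequence[Pose] | None = None,
    ratio_cutoff: float = SCORE_RATIO_CUTOFF,
    merge_radius: float = MERGE_RADIUS,
) -> Superligand:
    """Filter and merge docked poses; fall back to the crystallographic
    ligand's heavy atoms if no merged point survives."""
    if poses:
        passing = filter_poses(poses, ratio_cutoff)
        if passing:
            sl = merge_poses(passing, merge_radius)
            if sl.n_points > 0:
                return sl
    lig_atoms = pocket.ligand.heavy_atoms if pocket.ligand is not None else []
    if not lig_atoms:
        raise ValueError(
            f"pocket {pocket.pocket_id}: no poses passed the filters and the "
            "pocket has no reference ligand to fall back on"
        )
    points = np.array([a.position for a in lig_atoms])
    return Superligand(points=points, origin="crystal_ligand",
                       provenance=[pocket.ligand.name])


# --- built-in steric sampler -------------------------------------------------

def _lj_score(probe_pos: np.ndarray, receptor_pos: np.ndarray,
              receptor_tree: cKDTree) -> float:
    """Soft 6-12 Lennard-Jones with identical carbon parameters on every
    receptor atom; per-pair energy capped at +LJ_CLASH_CAP."""
    total = 0.0
    for p in probe_pos:
        idx = receptor_tree.query_ball_point(p, LJ_CUTOFF)
        if not idx:
            continue
        r = np.linalg.norm(receptor_pos[idx] - p, axis=1)
        r = np.maximum(r, 1e-6)
        s = (LJ_RMIN / r) ** 6
        e = LJ_EPSILON * (s * s - 2.0 * s)
        total += float(np.minimum(e, LJ_CLASH_CAP).sum())
    return total


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sample_steric_poses(
    pocket: Pocket,
    probe_library: Sequence[tuple[str, np.ndarray]],
    n_orientations: int = 200,
    seed: int = 0,
) -> list[Pose]:
    """Rigid-body steric sampler: random rotations and translations of each
    probe conformer inside the reference-ligand bounding box inflated by
    3 Å, scored with the soft Lennard-Jones above.  The best-scoring
    placement of each probe is returned as one :class:`Pose`.

    ``probe_library`` is a list of ``(name, (n, 3) heavy-atom coordinates)``
    tuples, e.g. from :func:`default_probe_library`.  Deterministic for a
    given seed.
    """
    if not probe_library:
        raise ValueError("probe library is empty")
    rng = np.random.default_rng(seed)
    receptor_pos = pocket.receptor_positions()
    tree = cKDTree(receptor_pos) if len(receptor_pos) else None
    lig_pos = np.array([a.position for a in pocket.ligand.heavy_atoms])
    lo = lig_pos.min(axis=0) - 3.0
    hi = lig_pos.max(axis=0) + 3.0
    poses: list[Pose] = []
    for name, coords in probe_library:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        centered = coords - coords.mean(axis=0)
        best_score = np.inf
        best_pos: np.ndarray | None = None
        for _ in range(n_orientations):
            rot = _random_rotation(rng)
            trans = rng.uniform(lo, hi)
            placed = centered @ rot.T + trans
            score = _lj_score(placed, receptor_pos, tree) if tree is not None else 0.0
            if score < best_score:
                best_score = score
                best_pos = placed
        if best_pos is None:  # no receptor: any placement scores 0
            best_score = 0.0
            best_pos = centered + (lo + hi) / 2.0
        poses.append(Pose(positions=best_pos, elements=["C"] * len(best_pos),
                          vdw_score=best_score, source_id=name))
    return poses


#: SMILES of a small library of rigid, drug-like probe molecules spanning
#: typical drug fragment shapes (flat aromatics, fused rings, short sp3
#: linkers).  3D conformers are generated on demand.
PROBE_SMILES = [
    ("benzene", "c1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("purine", "c1ncc2[nH]cnc2n1"),
    ("cyclohexane", "C1CCCCC1"),
    ("piperidine", "C1CCNCC1"),
    ("morpholine", "C1COCCN1"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("acetamide_phenyl", "CC(=O)Nc1ccccc1"),
    ("benzodioxole", "C1Oc2ccccc2O1"),
]


def default_probe_library(seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """Generate 3D heavy-atom conformers for the built-in probe library
    (one ETKDG conformer per molecule, deterministic for a given seed)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    library = []
    for name, smi in PROBE_SMILES:
        mol = Chem.MolFromSmiles(smi)
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31 - 1) + 1
        if AllChem.EmbedMolecule(mol, params) != 0:
            continue
        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        library.append((name, coords))
    return library


# --- pose I/O ----------------------------------------------------------------

def read_poses_sdf(path: str | Path, score_tag: str = "vdw_score") -> list[Pose]:
    """Read docked poses from a multi-molecule SDF; the steric score is taken
    from the ``score_tag`` SD property of each record."""
    from rdkit import Chem

    poses = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if not mol.HasProp(score_tag):
            raise ValueError(f"SDF record {i} lacks the '{score_tag}' property")
        score = float(mol.GetProp(score_tag))
        mol_noh = Chem.RemoveHs(mol)
        conf = mol_noh.GetConformer()
        coords = np.array([[conf.GetAtomPosition(j).x,
                            conf.GetAtomPosition(j).y,
                            conf.GetAtomPosition(j).z]
                           for j in range(mol_noh.GetNumAtoms())])
        elements = [a.GetSymbol() for a in mol_noh.GetAtoms()]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"pose{i}"
        poses.append(Pose(positions=coords, elements=elements,
                          vdw_score=score, source_id=name or f"pose{i}"))
    return poses


def write_superligand_pdb(sl: Superligand, path: str | Path) -> None:
    """Write superligand points as HETATM carbon records."""
    lines = [f"REMARK 900 SUPERLIGAND origin={sl.origin}"]
    for i, (x, y, z) in enumerate(sl.points, start=1):
        lines.append(
            f"HETATM{i:>5d}  C   SLG X{1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_superligand_pdb(path: str | Path) -> Superligand:
    origin = "merged_poses"
    points = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 900 SUPERLIGAND"):
            origin = line.split("origin=")[-1].strip()
        elif line.startswith(("HETATM", "ATOM")):
            points.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return Superligand(points=np.array(points), origin=origin)
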