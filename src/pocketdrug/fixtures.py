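"""Synthetic pockets and labelled descriptor tables for testing and demos.

Pockets are built from single-atom pseudo-residues carrying real residue
codes (glycine CA-like carbons for hydrophobic walls, glycine backbone-O
oxygens for polar walls) so that the polarity typing rules fire naturally,
arranged on simple geometries (deep cylinder, shallow groove, closed cage,
open plane) with ~3.5 Å spacing and a small carbon ligand at the cavity
centroid.  Each generated pocket comes with analytic labels: which wall
atoms line the cavity (are within occlusion reach of the ligand) and each
atom's intended polarity class.

Labelled descriptor tables emulate the druggability signal: druggable rows
have low relative polar surface area, high buried-superligand fraction and
high hydrophobic surface area; all remaining descriptors are uninformative
noise within their type ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import protor_radius
from .descriptors import DESCRIPTOR_NAMES
from .model import DRUGGABLE, LESS_DRUGGABLE, LabeledTable
from .structio import Atom, Pocket, Residue, ResidueClass, _pdb_atom_line
from .surface import PROBE_RADIUS

GEOMETRIES = ("deep_cylinder", "shallow_groove", "closed_cage", "open_plane")
WALL_SPACING = 3.5   # Å


@dataclass
class PocketSpec:
    geometry: str = "deep_cylinder"
    polarity_mix: float = 0.0      # fraction of polar wall atoms
    n_wall_atoms: int = 60
    seed: int = 0
    n_ligand_atoms: int = 4

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not 0.0 <= self.polarity_mix <= 1.0:
            raise ValueError("polarity_mix must be in [0, 1]")
        if self.n_wall_atoms < 10:
            raise ValueError("need at least 10 wall atoms")


def _wall_positions(spec: PocketSpec) -> tuple[np.ndarray, np.ndarray]:
    """Wall-atom coordinates and the ligand coordinates for a geometry."""
    n = spec.n_wall_atoms
    lig_n = spec.n_ligand_atoms
    if spec.geometry == "deep_cylinder":
        radius = 5.5
        per_ring = max(6, int(round(2 * math.pi * radius / WALL_SPACING)))
        walls = []
        z = 0.0
        ring = 0
        while len(walls) < n:
            offset = (ring % 2) * math.pi / per_ring
            for k in range(per_ring):
                ang = 2 * math.pi * k / per_ring + offset
                walls.append([radius * math.cos(ang), radius * math.sin(ang), z])
                if len(walls) >= n:
                    break
            z += WALL_SPACING
            ring += 1
        # ligand on the cylinder axis, midway up
        depth = z - WALL_SPACING
        lig = np.array([[0.0, 0.0, depth / 2 + 1.5 * (i - (lig_n - 1) / 2)]
                        for i in range(lig_n)])
        return np.array(walls), lig
    if spec.geometry == "closed_cage":
        radius = 5.0
        i = np.arange(n, dtype=float)
        phi = (1 + math.sqrt(5)) / 2
        zc = 1 - (2 * i + 1) / n
        theta = 2 * math.pi * i / phi
        r = np.sqrt(np.maximum(0, 1 - zc * zc))
        walls = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), zc])
        lig = np.array([[1.0 * (i - (lig_n - 1) / 2) * 0.8, 0.0, 0.0]
                        for i in range(lig_n)])
        if np.linalg.norm(lig, axis=1).max() > radius - 2.5:
            raise ValueError("cavity smaller than ligand")
        return walls, lig
    # planar geometries
    side = int(math.ceil(math.sqrt(n)))
    xs = (np.arange(side) - (side - 1) / 2) * WALL_SPACING
    walls = []
    for x in xs:
        for y in xs:
            walls.append([x, y, 0.0])
            if len(walls) >= n:
                break
        if len(walls) >= n:
            break
    walls = np.array(walls)
    if spec.geometry == "shallow_groove":
        # depress the central atoms to form a shallow trough
        centre = np.linalg.norm(walls[:, :2], axis=1) < 1.5 * WALL_SPACING
        walls[centre, 2] -= 2.0
        lig_z = 1.5
    else:  # open_plane
        lig_z = 4.0
    lig = np.array([[1.5 * (i - (lig_n - 1) / 2), 0.0, lig_z] for i in range(lig_n)])
    return walls, lig


def make_synthetic_pocket(spec: PocketSpec) -> tuple[str, dict]:
    """Generate a synthetic pocket as PDB text plus analytic labels.

    Labels: ``lining`` — wall residue numbers within occlusion reach of the
    ligand (their SASA must change when the ligand-derived superligand is
    present); ``polarity`` — wall residue number → intended polarity class
    ("hydrophobic"/"polar"); ``n_wall_atoms`` and ``n_ligand_atoms`` for
    bookkeeping.  Deterministic for a given seed.
    """
    walls, lig = _wall_positions(spec)
    rng = np.random.default_rng(spec.seed)
    n = len(walls)
    n_polar = int(round(spec.polarity_mix * n))
    polar_idx = set(rng.choice(n, size=n_polar, replace=False).tolist())
    lines = ["REMARK 900 POCKET synthetic", "REMARK 900 LIGAND L:1:LIG"]
    polarity: dict[int, str] = {}
    serial = 0
    for i, pos in enumerate(walls):
        seq = i + 1
        polar = i in polar_idx
        res = Residue(name="GLY", chain_id="W", seq_id=seq,
                      residue_class=ResidueClass.AMINO_ACID)
        atom = Atom(element="O" if polar else "C", position=pos,
                    name="O" if polar else "CA", residue=res)
        res.atoms.append(atom)
        serial += 1
        lines.append(_pdb_atom_line("ATOM", serial, atom, res))
        polarity[seq] = "polar" if polar else "hydrophobic"
    lig_res = Residue(name="LIG", chain_id="L", seq_id=1,
                      residue_class=ResidueClass.LIGAND)
    for j, pos in enumerate(lig):
        atom = Atom(element="C", position=pos, name=f"C{j + 1}", residue=lig_res)
        lig_res.atoms.append(atom)
        serial += 1
        lines.append(_pdb_atom_line("HETATM", serial, atom, lig_res))
    lines.append("END")
    # occlusion-reach labelling: a wall atom's SASA can change iff its
    # extended sphere overlaps an extended superligand sphere
    sl_radius = 1.88
    lining = []
    for i, pos in enumerate(walls):
        r_wall = protor_radius("O", "GLY", "O") if i in polar_idx else protor_radius("C", "GLY", "CA")
        reach = (r_wall + PROBE_RADIUS) + (sl_radius + PROBE_RADIUS)
        if np.linalg.norm(lig - pos, axis=1).min() < reach:
            lining.append(i + 1)
    labels = {
        "lining": lining,
        "polarity": polarity,
        "n_wall_atoms": n,
        "n_ligand_atoms": len(lig),
    }
    return "\n".join(lines) + "\n", labels


def synthetic_pocket(spec: PocketSpec) -> tuple[Pocket, dict]:
    """In-memory variant of :func:`make_synthetic_pocket`: the same pocket
    as a :class:`Pocket` object plus the analytic labels."""
    text, labels = make_synthetic_pocket(spec)
    import io
    import tempfile
    from .structio import read_pocket_pdb
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(text)
        path = fh.name
    pocket = read_pocket_pdb(path)
    import os
    os.unlink(path)
    return pocket, labels


# --- labelled descriptor tables ---------------------------------------------

#: descriptors that carry the generative druggability signal, with the sign
#: of their association with druggability
INFORMATIVE_DESCRIPTORS = {"psa_r": -1, "fr_buried_sl_atoms": +1, "hsa": +1}


def make_labeled_table(n: int = 200, effect: float = 1.0, noise_sd: float = 0.1,
                       seed: int = 0) -> LabeledTable:
    """Synthetic labelled descriptor table with a known generative signal.

    Druggable rows have low ``psa_r``, high ``fr_buried_sl_atoms`` and high
    ``hsa`` (mean shift scaled by ``effect``); every other descriptor is
    label-independent noise within its type range.  ``effect=0`` makes the
    classes indistinguishable.  Values respect all descriptor invariants
    (fractions clipped to [0, 1], counts positive).
    """
    if n < 20:
        raise ValueError("need at least 20 rows")
    rng = np.random.default_rng(seed)
    n_d = n // 2
    y = np.array([1] * n_d + [0] * (n - n_d))
    rng.shuffle(y)
    shift = 0.15 * min(effect, 10.0)
    data: dict[str, np.ndarray] = {}
    sign = np.where(y == 1, 1.0, -1.0)
    data["psa_r"] = np.clip(rng.normal(0.5 - sign * shift, noise_sd), 0, 1)
    data["fr_buried_sl_atoms"] = np.clip(rng.normal(0.5 + sign * shift, noise_sd), 0, 1)
    data["hsa"] = np.clip(rng.normal(300 + sign * shift * 600, noise_sd * 600), 0, None)
    data["fr_hpb_atoms"] = rng.uniform(0, 1, n)
    data["sa_vol_r"] = rng.uniform(0.4, 1.6, n)
    data["exp_sl_sa"] = rng.uniform(20, 400, n)
    data["sl_bs_r"] = rng.uniform(0.05, 1.0, n)
    data["no_bs_atoms"] = rng.integers(20, 150, n).astype(float)
    data["no_sl_atoms"] = rng.integers(5, 100, n).astype(float)
    data["InertialShapeFactor"] = rng.uniform(0, 0.05, n)
    data["SpherocityIndex"] = rng.uniform(0, 1, n)
    data["PMI3"] = rng.uniform(100, 6000, n)
    rows = pd.DataFrame({k: data[k] for k in DESCRIPTOR_NAMES},
                        index=[f"pocket{i:04d}" for i in range(n)])
    labels = pd.Series(np.where(y == 1, DRUGGABLE, LESS_DRUGGABLE),
                       index=rows.index, name="label")
    return LabeledTable(rows, labels)
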