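"""Solvent-accessible surface areas and pocket polarity analysis.

The SASA engine is a Shrake–Rupley implementation over united-atom ProtOr
radii with a 1.0 Å water probe: each atom's extended sphere is sampled on a
deterministic Fibonacci lattice (960 points by default) and a sample point
counts as accessible if it lies outside every neighbouring extended sphere.

On top of it sit the pocket-analysis primitives:

* binding-site atoms — receptor atoms whose SASA changes when the
  superligand is added;
* surface vs buried superligand atoms — superligand points with positive
  vs zero SASA in the presence of the receptor;
* polarity typing — C/P/S and glycosidic base nitrogens are hydrophobic;
  amino-acid, ribose and phosphate oxygens and nonaromatic amino-acid
  nitrogens are polar; endocyclic aromatic nitrogens (bases, His, Trp) and
  exocyclic base O/N are ambivalent and get their SASA split;
* the blocking-carbon split — the ambivalent atoms' SASA is recomputed with
  two carbon spheres placed 1.70 Å above and below the ring plane, so that
  the remaining (in-plane, hydrogen-bonding) area counts as polar and the
  blocked (stacking) area as hydrophobic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (
    AA_AROMATIC_N,
    ENDOCYCLIC_AROMATIC_N,
    EXOCYCLIC_BASE_ON,
    GLYCOSIDIC_N,
    RING_ATOMS,
    SUPERLIGAND_POINT_RADIUS,
    protor_radius,
)
from .structio import Atom, Pocket, Residue, ResidueClass
from .superligand import Superligand

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.0
N_SPHERE_POINTS = 960
DSASA_TOL = 1e-6
BLOCKER_DISTANCE = 1.70


class PolarityClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    POLAR = "polar"
    SPLIT = "split"


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice with n points."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom_area: np.ndarray
    probe_radius: float
    radii_set: str = "ProtOr"

    def total(self) -> float:
        return float(self.per_atom_area.sum())


def compute_sasa(
    positions: np.ndarray,
    radii: np.ndarray | float,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    subset: np.ndarray | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA for a set of spheres.

    Parameters
    ----------
    positions : (n, 3) sphere centres in Å.
    radii : per-sphere van der Waals radii (scalar broadcast allowed).
    probe : probe radius in Å.
    n_points : Fibonacci-lattice sample count per sphere.
    subset : optional indices; areas are computed only for these spheres
        (others still occlude).  The returned array always has length n,
        with zeros outside the subset.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    if n == 0:
        return SasaResult(np.zeros(0), probe)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    extended = radii + probe
    sphere = fibonacci_sphere(n_points)
    areas = np.zeros(n)
    tree = cKDTree(positions)
    max_ext = extended.max()
    targets = range(n) if subset is None else np.asarray(subset, dtype=int)
    for i in targets:
        ri = extended[i]
        neighbours = tree.query_ball_point(positions[i], ri + max_ext)
        neighbours = [j for j in neighbours if j != i]
        pts = positions[i] + ri * sphere
        if neighbours:
            accessible = np.ones(n_points, dtype=bool)
            for j in neighbours:
                d = positions[j] - positions[i]
                dist = np.linalg.norm(d)
                if dist >= ri + extended[j]:
                    continue
                if dist < 1e-12 and abs(extended[j] - ri) < 1e-12:
                    # coincident equal spheres: bury all but the first
                    if j < i:
                        accessible[:] = False
                        break
                    continue
                if dist + ri <= extended[j]:
                    accessible[:] = False
                    break
                inside = np.einsum("ij,ij->i", pts - positions[j], pts - positions[j]) < extended[j] ** 2
                accessible &= ~inside
                if not accessible.any():
                    break
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * ri * ri
    return SasaResult(areas, probe)


def _atom_radii(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([
        protor_radius(a.element, a.residue.name if a.residue else None, a.name)
        for a in atoms
    ])


def _positions(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)


def receptor_sasa(pocket: Pocket, sl: Superligand | None = None,
                  probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom SASA of the pocket's receptor atoms, optionally with the
    superligand present as additional occluding carbon spheres."""
    atoms = pocket.all_occluding_atoms
    pos = _positions(atoms)
    radii = _atom_radii(atoms)
    n_rec = len(pocket.receptor_atoms)
    if sl is not None and sl.n_points:
        pos = np.vstack([pos, sl.points])
        radii = np.concatenate([radii, np.full(sl.n_points, SUPERLIGAND_POINT_RADIUS)])
    res = compute_sasa(pos, radii, probe=probe, n_points=n_points,
                       subset=np.arange(n_rec))
    return res.per_atom_area[:n_rec]


def assign_binding_site_atoms(
    pocket: Pocket,
    sl: Superligand,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    tol: float = DSASA_TOL,
) -> set[Atom]:
    """Receptor atoms whose SASA differs between the superligand-bound and
    -unbound states (|ΔSASA| > tol)."""
    unbound = receptor_sasa(pocket, None, probe, n_points)
    bound = receptor_sasa(pocket, sl, probe, n_points)
    diff = np.abs(bound - unbound) > tol
    return {a for a, flag in zip(pocket.receptor_atoms, diff) if flag}


def classify_superligand_atoms(
    pocket: Pocket,
    sl: Superligand,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    tol: float = DSASA_TOL,
) -> tuple[set[int], set[int]]:
    """Partition superligand point indices into (surface, buried) by their
    SASA in the presence of the receptor: positive SASA → surface, zero →
    buried."""
    areas = superligand_sasa(pocket, sl, probe, n_points)
    surface = {i for i, a in enumerate(areas) if a > tol}
    buried = {i for i in range(sl.n_points) if i not in surface}
    return surface, buried


def superligand_sasa(pocket: Pocket, sl: Superligand,
                     probe: float = PROBE_RADIUS,
                     n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-point SASA of the superligand in the presence of the receptor."""
    atoms = pocket.all_occluding_atoms
    pos = np.vstack([_positions(atoms), sl.points]) if atoms else sl.points
    radii = np.concatenate([
        _atom_radii(atoms),
        np.full(sl.n_points, SUPERLIGAND_POINT_RADIUS),
    ]) if atoms else np.full(sl.n_points, SUPERLIGAND_POINT_RADIUS)
    n_rec = len(atoms)
    res = compute_sasa(pos, radii, probe=probe, n_points=n_points,
                       subset=np.arange(n_rec, n_rec + sl.n_points))
    return res.per_atom_area[n_rec:]


# --- polarity ----------------------------------------------------------------

def _parent_code(residue: Residue) -> str:
    if residue.residue_class is ResidueClass.MODIFIED_NUCLEOTIDE:
        return residue.parent_code or residue.name
    return residue.name


def type_atom_polarity(residue: Residue, atom: Atom) -> PolarityClass:
    """Assign a heavy atom to the hydrophobic / polar / split polarity class.

    Hydrophobic: all C, P and S, plus the glycosidic base nitrogen (the
    nitrogen bound to the ribose: N9 of purines, N1 of pyrimidines).
    Polar: amino-acid oxygens, ribose and phosphate oxygens, and nonaromatic
    amino-acid nitrogens.
    Split (ambivalent): endocyclic aromatic nitrogens of the bases and of
    His/Trp side chains, and exocyclic base oxygens and nitrogens.
    """
    el = atom.element.upper()
    name = atom.name.upper()
    code = _parent_code(residue)
    if el in ("C", "P", "S"):
        return PolarityClass.HYDROPHOBIC
    is_nt = residue.residue_class in (ResidueClass.NUCLEOTIDE,
                                      ResidueClass.MODIFIED_NUCLEOTIDE)
    is_aa = residue.residue_class is ResidueClass.AMINO_ACID
    if is_nt:
        if el == "N":
            if name == GLYCOSIDIC_N.get(code):
                return PolarityClass.HYDROPHOBIC
            if name in ENDOCYCLIC_AROMATIC_N.get(code, set()):
                return PolarityClass.SPLIT
            if name in EXOCYCLIC_BASE_ON.get(code, set()):
                return PolarityClass.SPLIT
            return PolarityClass.POLAR
        if el == "O":
            if name in EXOCYCLIC_BASE_ON.get(code, set()):
                return PolarityClass.SPLIT
            return PolarityClass.POLAR  # ribose and phosphate oxygens
    if is_aa:
        if el == "O":
            return PolarityClass.POLAR
        if el == "N":
            if name in AA_AROMATIC_N.get(code, set()):
                return PolarityClass.SPLIT
            return PolarityClass.POLAR
    # unmapped atom: fall back to an element default
    logger.warning("unmapped atom %s/%s (%s): polarity by element default",
                   residue.name, atom.name, el)
    return PolarityClass.POLAR if el in ("N", "O") else PolarityClass.HYDROPHOBIC


def fit_ring_plane(ring_positions: np.ndarray) -> np.ndarray:
    """Least-squares plane fit: returns the unit normal of the best-fit
    plane through the ring atoms.  Raises on degenerate (collinear) rings."""
    pts = np.asarray(ring_positions, dtype=float)
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) ring: cannot fit a plane")
    return vt[2]


def split_aromatic_sasa(
    pocket: Pocket,
    atom: Atom,
    ring_atoms: Sequence[Atom],
    blocker_distance: float = BLOCKER_DISTANCE,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> tuple[float, float]:
    """Blocking-carbon SASA split for an ambivalent aromatic atom.

    Two carbon spheres are placed perpendicular to the aromatic ring plane
    at ``blocker_distance`` from the atom of interest.  The atom's SASA with
    the blockers present is the polar part (in-plane, hydrogen-bonding);
    the remainder of its total SASA is the hydrophobic (stacking) part.
    Blockers occlude but contribute no area.  Returns (sasa_pol, sasa_hpb).
    """
    if len(ring_atoms) < 5:
        raise ValueError("aromatic ring must have at least 5 atoms")
    normal = fit_ring_plane(np.array([a.position for a in ring_atoms]))
    blockers = np.array([
        atom.position + blocker_distance * normal,
        atom.position - blocker_distance * normal,
    ])
    atoms = pocket.all_occluding_atoms
    try:
        idx = atoms.index(atom)
    except ValueError:
        raise ValueError("atom is not part of the pocket's receptor") from None
    pos = _positions(atoms)
    radii = _atom_radii(atoms)
    total = compute_sasa(pos, radii, probe=probe, n_points=n_points,
                         subset=np.array([idx])).per_atom_area[idx]
    pos_b = np.vstack([pos, blockers])
    radii_b = np.concatenate([radii, [SUPERLIGAND_POINT_RADIUS] * 2])
    pol = compute_sasa(pos_b, radii_b, probe=probe, n_points=n_points,
                       subset=np.array([idx])).per_atom_area[idx]
    return float(pol), float(total - pol)


def _ring_atoms_for(atom: Atom, residue: Residue) -> list[Atom] | None:
    """Atoms of the aromatic ring system attached to (or containing) a split
    atom, for the plane fit; ``None`` if the ring cannot be resolved."""
    names = RING_ATOMS.get(_parent_code(residue))
    if not names:
        return None
    by_name = {a.name.upper(): a for a in residue.heavy_atoms}
    ring = [by_name[n] for n in names if n in by_name]
    return ring if len(ring) >= 5 else None


@dataclass
class AtomSurfaceRecord:
    atom: Atom
    polarity: PolarityClass
    sasa_total: float
    sasa_pol: float
    sasa_hpb: float
    is_binding_site: bool

    @property
    def hydrophobic_fraction(self) -> float | None:
        """Fraction of the atom's SASA that is hydrophobic; None when the
        atom has zero total SASA (fully buried)."""
        if self.sasa_total <= 0.0:
            return None
        return self.sasa_hpb / self.sasa_total


@dataclass
class SurfaceAnalysis:
    """Full per-atom surface bookkeeping for one pocket + superligand pair."""

    pocket: Pocket
    superligand: Superligand
    records: list[AtomSurfaceRecord]
    sl_surface: set[int]
    sl_buried: set[int]
    sl_areas: np.ndarray
    probe: float = PROBE_RADIUS
    n_points: int = N_SPHERE_POINTS

    @property
    def binding_site_records(self) -> list[AtomSurfaceRecord]:
        return [r for r in self.records if r.is_binding_site]

    @property
    def exp_sl_sa(self) -> float:
        """Total SASA of the superligand's surface points in the complex."""
        return float(sum(self.sl_areas[i] for i in self.sl_surface))


def analyze_surface(
    pocket: Pocket,
    sl: Superligand,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    tol: float = DSASA_TOL,
) -> SurfaceAnalysis:
    """Run the full surface workflow for one pocket: receptor SASA in the
    bound and unbound state, binding-site assignment, polarity typing with
    the blocking-carbon split, and superligand surface/buried partition.

    Metals (when a metal variant is analysed) occlude surface but are
    excluded from polarity classes and from all polarity bookkeeping.
    """
    unbound = receptor_sasa(pocket, None, probe, n_points)
    bound = receptor_sasa(pocket, sl, probe, n_points)
    bs_flags = np.abs(bound - unbound) > tol
    records: list[AtomSurfaceRecord] = []
    for atom, area, is_bs in zip(pocket.receptor_atoms, unbound, bs_flags):
        residue = atom.residue
        if residue is None or residue.residue_class is ResidueClass.METAL:
            continue
        pol = type_atom_polarity(residue, atom)
        if pol is PolarityClass.HYDROPHOBIC:
            sasa_pol, sasa_hpb = 0.0, float(area)
        elif pol is PolarityClass.POLAR:
            sasa_pol, sasa_hpb = float(area), 0.0
        else:
            ring = _ring_atoms_for(atom, residue)
            if ring is None or area <= tol:
                # fully buried or unresolvable ring: split is moot
                sasa_pol, sasa_hpb = float(area), 0.0
            else:
                sasa_pol, sasa_hpb = split_aromatic_sasa(
                    pocket, atom, ring, probe=probe, n_points=n_points)
        records.append(AtomSurfaceRecord(
            atom=atom, polarity=pol, sasa_total=float(area),
            sasa_pol=sasa_pol, sasa_hpb=sasa_hpb, is_binding_site=bool(is_bs)))
    sl_areas = superligand_sasa(pocket, sl, probe, n_points)
    surface = {i for i, a in enumerate(sl_areas) if a > tol}
    buried = set(range(sl.n_points)) - surface
    return SurfaceAnalysis(pocket=pocket, superligand=sl, records=records,
                           sl_surface=surface, sl_buried=buried,
                           sl_areas=sl_areas, probe=probe, n_points=n_points)


def hydrophobic_bs_atom_count(analysis: SurfaceAnalysis) -> int:
    """Number of binding-site atoms whose SASA is more than half hydrophobic.

    Hydrophobic-class atoms count as fraction 1 and polar-class as 0; split
    atoms use their blocking-carbon ratio.  Atoms with zero total SASA are
    counted by their element class (C/P/S hydrophobic)."""
    count = 0
    for rec in analysis.binding_site_records:
        frac = rec.hydrophobic_fraction
        if frac is None:
            if rec.atom.element.upper() in ("C", "P", "S"):
                count += 1
        elif frac > 0.5:
            count += 1
    return count


def monte_carlo_sasa(
    positions: np.ndarray,
    radii: np.ndarray | float,
    probe: float = PROBE_RADIUS,
    n_samples: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Independent Monte-Carlo SASA estimate: uniform random points on each
    extended sphere, rejected if inside any other extended sphere.  Used as
    a cross-check oracle for :func:`compute_sasa`."""
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    extended = radii + probe
    areas = np.zeros(n)
    for i in range(n):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = positions[i] + extended[i] * v
        outside = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - positions[j], pts - positions[j])
            outside &= d2 >= extended[j] ** 2
        areas[i] = outside.mean() * 4.0 * math.pi * extended[i] ** 2
    return areas
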