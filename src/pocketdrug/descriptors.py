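"""The 12-descriptor vector characterising a pocket via its superligand.

Polarity descriptors (``psa_r``, ``fr_hpb_atoms``, ``hsa``) come from the
binding-site atoms' polar/hydrophobic SASA bookkeeping; size and burial
descriptors (``no_bs_atoms``, ``no_sl_atoms``, ``sl_bs_r``,
``fr_buried_sl_atoms``, ``exp_sl_sa``, ``sa_vol_r``) count and measure the
superligand negative print; shape descriptors (``PMI3``,
``SpherocityIndex``, ``InertialShapeFactor``) are the standard 3D shape
terms of the superligand point set with unit masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .structio import Pocket
from .superligand import Superligand
from .surface import (
    N_SPHERE_POINTS,
    PROBE_RADIUS,
    SurfaceAnalysis,
    analyze_surface,
    compute_sasa,
    hydrophobic_bs_atom_count,
)

#: canonical descriptor order (also the CSV header)
DESCRIPTOR_NAMES = [
    "psa_r",
    "fr_hpb_atoms",
    "fr_buried_sl_atoms",
    "sa_vol_r",
    "exp_sl_sa",
    "sl_bs_r",
    "hsa",
    "no_bs_atoms",
    "no_sl_atoms",
    "InertialShapeFactor",
    "SpherocityIndex",
    "PMI3",
]

SL_SPHERE_RADIUS = 1.7   # Å, union-of-spheres radius for sa_vol_r
SL_GRID_SPACING = 0.3    # Å, voxel grid for the superligand volume


@dataclass
class DescriptorVector:
    psa_r: float
    fr_hpb_atoms: float
    fr_buried_sl_atoms: float
    sa_vol_r: float
    exp_sl_sa: float
    sl_bs_r: float
    hsa: float
    no_bs_atoms: int
    no_sl_atoms: int
    InertialShapeFactor: float
    SpherocityIndex: float
    PMI3: float

    def __post_init__(self) -> None:
        for name in ("psa_r", "fr_hpb_atoms", "fr_buried_sl_atoms"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.SpherocityIndex <= 1.0 + 1e-9:
            raise ValueError(f"SpherocityIndex={self.SpherocityIndex} outside [0,1]")
        if self.PMI3 < 0 or self.no_bs_atoms < 0 or self.no_sl_atoms < 0:
            raise ValueError("negative count or moment")

    def to_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: d[k] for k in DESCRIPTOR_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DESCRIPTOR_NAMES], dtype=float)


def union_of_spheres_volume(points: np.ndarray, radius: float = SL_SPHERE_RADIUS,
                            spacing: float = SL_GRID_SPACING) -> float:
    """Volume of the union of equal spheres by voxel counting on a regular
    grid: a voxel contributes if its centre lies inside any sphere."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    lo = points.min(axis=0) - radius - spacing
    hi = points.max(axis=0) + radius + spacing
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    from scipy.spatial import cKDTree
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centres = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(points)
    d, _ = tree.query(centres, k=1)
    inside = int((d <= radius).sum())
    return inside * spacing ** 3


def union_of_spheres_area(points: np.ndarray, radius: float = SL_SPHERE_RADIUS,
                          n_points: int = N_SPHERE_POINTS) -> float:
    """Surface area of the union of equal spheres (zero-probe SASA)."""
    res = compute_sasa(points, radius, probe=0.0, n_points=n_points)
    return res.total()


def shape_descriptors(points: np.ndarray,
                      grid_spacing: float = SL_GRID_SPACING) -> tuple[float, float, float, float]:
    """Shape terms of a point set with unit masses.

    Returns ``(PMI3, SpherocityIndex, InertialShapeFactor, sa_vol_r)``:

    * principal moments of inertia I1 ≤ I2 ≤ I3 about the centroid;
      PMI3 = I3 and InertialShapeFactor = I2/(I1·I3) (0 when I1 = 0);
    * SpherocityIndex = 3·λ_min/(λ1+λ2+λ3) from the covariance eigenvalues
      (0 when all points coincide);
    * sa_vol_r = union-of-spheres surface area / volume with 1.7 Å radii.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("shape descriptors need at least one point")
    centred = points - points.mean(axis=0)
    # inertia tensor with unit masses
    r2 = np.einsum("ij,ij->i", centred, centred)
    inertia = np.eye(3) * r2.sum() - centred.T @ centred
    moments = np.sort(np.linalg.eigvalsh(inertia))
    i1, i2, i3 = (max(0.0, m) for m in moments)
    pmi3 = i3
    isf = i2 / (i1 * i3) if i1 > 1e-12 and i3 > 1e-12 else 0.0
    cov = centred.T @ centred / len(points)
    lam = np.sort(np.linalg.eigvalsh(cov))
    tot = lam.sum()
    spherocity = 3.0 * max(0.0, lam[0]) / tot if tot > 1e-12 else 0.0
    area = union_of_spheres_area(points)
    volume = union_of_spheres_volume(points, spacing=grid_spacing)
    sa_vol_r = area / volume if volume > 0 else 0.0
    return pmi3, min(1.0, spherocity), isf, sa_vol_r


def compute_descriptors(
    pocket: Pocket,
    sl: Superligand,
    analysis: SurfaceAnalysis | None = None,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> DescriptorVector:
    """Compute the full 12-descriptor vector for a pocket + superligand.

    A precomputed :class:`SurfaceAnalysis` can be passed to avoid repeating
    the SASA work; otherwise one is computed here.
    """
    if analysis is None:
        analysis = analyze_surface(pocket, sl, probe=probe, n_points=n_points)
    bs = analysis.binding_site_records
    if not bs:
        raise ValueError(f"pocket {pocket.pocket_id}: no binding-site atoms "
                         "(degenerate pocket)")
    sasa_total_bs = sum(r.sasa_total for r in bs)
    sasa_pol_bs = sum(r.sasa_pol for r in bs)
    hsa = sum(r.sasa_hpb for r in bs)
    psa_r = sasa_pol_bs / sasa_total_bs if sasa_total_bs > 0 else 0.0
    no_bs = len(bs)
    no_sl = sl.n_points
    n_hpb = hydrophobic_bs_atom_count(analysis)
    fr_hpb = n_hpb / no_bs
    fr_buried = len(analysis.sl_buried) / no_sl if no_sl else 0.0
    pmi3, spherocity, isf, sa_vol_r = shape_descriptors(sl.points)
    return DescriptorVector(
        psa_r=min(1.0, psa_r),
        fr_hpb_atoms=fr_hpb,
        fr_buried_sl_atoms=fr_buried,
        sa_vol_r=sa_vol_r,
        exp_sl_sa=analysis.exp_sl_sa,
        sl_bs_r=no_sl / no_bs,
        hsa=hsa,
        no_bs_atoms=no_bs,
        no_sl_atoms=no_sl,
        InertialShapeFactor=isf,
        SpherocityIndex=spherocity,
        PMI3=pmi3,
    )
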