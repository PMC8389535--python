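"""SASA engine, binding-site assignment, polarity typing, blocking split."""

import math

import numpy as np
import pytest

from conftest import make_point_pocket, make_residue
from pocketdrug.structio import ResidueClass
from pocketdrug.superligand import Superligand, build_superligand
from pocketdrug.surface import (
    PolarityClass,
    analyze_surface,
    assign_binding_site_atoms,
    classify_superligand_atoms,
    compute_sasa,
    fibonacci_sphere,
    hydrophobic_bs_atom_count,
    monte_carlo_sasa,
    split_aromatic_sasa,
    type_atom_polarity,
)


def test_single_sphere_closed_form():
    res = compute_sasa(np.zeros((1, 3)), 1.88, probe=1.0)
    assert res.per_atom_area[0] == pytest.approx(4 * math.pi * 2.88**2, rel=1e-12)


def test_distant_spheres_are_isolated():
    pos = np.array([[0, 0, 0], [100, 0, 0]])
    res = compute_sasa(pos, 1.88, probe=1.0)
    iso = 4 * math.pi * 2.88**2
    np.testing.assert_allclose(res.per_atom_area, [iso, iso], rtol=1e-12)


def test_coincident_spheres_one_buried():
    pos = np.zeros((2, 3))
    res = compute_sasa(pos, 1.88, probe=1.0)
    assert sorted(res.per_atom_area) == pytest.approx(
        [0.0, 4 * math.pi * 2.88**2], rel=1e-12)


def test_zero_atoms_empty_result():
    res = compute_sasa(np.zeros((0, 3)), 1.88)
    assert res.per_atom_area.size == 0


def test_two_overlapping_spheres_match_closed_form():
    """For two equal spheres the accessible area has a closed form: each
    sphere loses a cap of height h = R - d/2."""
    r, probe, d = 1.7, 1.0, 2.0
    R = r + probe
    res = compute_sasa(np.array([[0, 0, 0], [d, 0, 0]]), r, probe=probe)
    cap = 2 * math.pi * R * (R - d / 2)
    expected = 4 * math.pi * R**2 - cap
    np.testing.assert_allclose(res.per_atom_area, expected, rtol=2e-3)


def test_sasa_matches_monte_carlo_oracle():
    rng = np.random.default_rng(0)
    for seed in range(5):
        n = int(rng.integers(5, 15))
        pos = rng.uniform(0, 6, size=(n, 3))
        radii = rng.uniform(1.4, 1.9, size=n)
        mine = compute_sasa(pos, radii, probe=1.0).per_atom_area
        oracle = monte_carlo_sasa(pos, radii, probe=1.0, n_samples=50_000,
                                  seed=seed)
        assert abs(mine.sum() - oracle.sum()) / oracle.sum() < 0.01


def test_sasa_matches_biotite():
    """Independent cross-check against biotite's Shrake-Rupley."""
    import biotite.structure as struc

    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 8, size=(12, 3))
    arr = struc.AtomArray(12)
    arr.coord = pos.astype(np.float32)
    arr.element = np.array(["C"] * 12)
    arr.res_name = np.array(["LIG"] * 12)
    arr.atom_name = np.array([f"C{i}" for i in range(12)])
    arr.res_id = np.ones(12, dtype=int)
    ref = struc.sasa(arr, probe_radius=1.0, point_number=2000,
                     vdw_radii=np.full(12, 1.88))
    mine = compute_sasa(pos, 1.88, probe=1.0, n_points=2000).per_atom_area
    np.testing.assert_allclose(mine, ref, rtol=0.02, atol=0.5)


def test_occlusion_monotonicity():
    """Adding any sphere never increases an existing atom's SASA."""
    rng = np.random.default_rng(2)
    pos = rng.uniform(0, 6, size=(10, 3))
    base = compute_sasa(pos, 1.7).per_atom_area
    for _ in range(5):
        extra = np.vstack([pos, rng.uniform(0, 6, size=(1, 3))])
        more = compute_sasa(extra, 1.7).per_atom_area[:10]
        assert np.all(more <= base + 1e-9)


def test_fibonacci_lattice_is_unit_sphere():
    pts = fibonacci_sphere(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, rtol=1e-12)
    # near-uniform: centroid close to origin
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


# --- binding-site assignment -------------------------------------------------

def test_far_atom_is_not_binding_site():
    pocket = make_point_pocket([[50, 0, 0], [3.5, 0, 0]], [[0, 0, 0]])
    sl = build_superligand(pocket, None)
    bs = assign_binding_site_atoms(pocket, sl)
    seqs = {a.residue.seq_id for a in bs}
    assert seqs == {2}


def test_contact_atom_is_binding_site():
    pocket = make_point_pocket([[4.0, 0, 0]], [[0, 0, 0]])
    sl = build_superligand(pocket, None)
    bs = assign_binding_site_atoms(pocket, sl)
    assert len(bs) == 1


def test_cylinder_binding_site_matches_analytic_labels(cylinder_pocket):
    pocket, labels = cylinder_pocket
    sl = build_superligand(pocket, None)
    bs = assign_binding_site_atoms(pocket, sl)
    assert sorted(a.residue.seq_id for a in bs) == sorted(labels["lining"])


def test_binding_site_invariant_under_rigid_motion(cylinder_pocket):
    from scipy.spatial.transform import Rotation

    pocket, _ = cylinder_pocket
    sl = build_superligand(pocket, None)
    ref = {a.residue.seq_id for a in assign_binding_site_atoms(pocket, sl)}
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    shift = np.array([13.0, -7.0, 4.0])
    for atom in pocket.receptor_atoms + pocket.ligand.atoms:
        atom.position = rot @ atom.position + shift
    sl2 = build_superligand(pocket, None)
    moved = {a.residue.seq_id for a in assign_binding_site_atoms(pocket, sl2)}
    assert moved == ref


# --- superligand atom classification ----------------------------------------

def test_lone_superligand_point_is_surface():
    pocket = make_point_pocket([[50, 0, 0]], [[0, 0, 0]])
    sl = Superligand(points=np.array([[0.0, 0, 0]]), origin="crystal_ligand")
    surface, buried = classify_superligand_atoms(pocket, sl)
    assert surface == {0} and buried == set()


def test_caged_point_is_buried():
    cage = fibonacci_sphere(40) * 4.0
    pocket = make_point_pocket(cage.tolist(), [[0, 0, 0]])
    sl = Superligand(points=np.array([[0.0, 0, 0]]), origin="crystal_ligand")
    surface, buried = classify_superligand_atoms(pocket, sl)
    assert buried == {0} and surface == set()


def test_half_buried_slab_counts():
    """Points under a dense slab are buried, points far above are surface."""
    xs = np.arange(-7, 7.5, 1.5)
    slab = [[x, y, 0.0] for x in xs for y in xs]
    pocket = make_point_pocket(slab, [[0, 0, 20]])
    pts = np.array([[0, 0, 1.0], [1.5, 0, 1.0],      # resting on the slab
                    [0, 0, 30.0], [3, 0, 30.0]])     # free in solvent
    sl = Superligand(points=pts, origin="merged_poses")
    surface, buried = classify_superligand_atoms(pocket, sl)
    assert {2, 3} <= surface          # far points always surface
    assert surface | buried == {0, 1, 2, 3}
    assert surface & buried == set()


# --- polarity ---------------------------------------------------------------

def _nt_residue(code, atoms):
    return make_residue(code, "B", 1, ResidueClass.NUCLEOTIDE, atoms)


@pytest.mark.parametrize("res_code,atom_name,element,expected", [
    ("A", "N9", "N", PolarityClass.HYDROPHOBIC),   # glycosidic
    ("A", "N1", "N", PolarityClass.SPLIT),         # endocyclic aromatic
    ("A", "N6", "N", PolarityClass.SPLIT),         # exocyclic
    ("G", "O6", "O", PolarityClass.SPLIT),
    ("G", "C8", "C", PolarityClass.HYDROPHOBIC),
    ("U", "O2'", "O", PolarityClass.POLAR),        # ribose oxygen
    ("U", "OP1", "O", PolarityClass.POLAR),        # phosphate oxygen
    ("C", "N4", "N", PolarityClass.SPLIT),
    ("A", "P", "P", PolarityClass.HYDROPHOBIC),
])
def test_nucleotide_polarity(res_code, atom_name, element, expected):
    res = _nt_residue(res_code, [(atom_name, element, (0, 0, 0))])
    assert type_atom_polarity(res, res.atoms[0]) is expected


@pytest.mark.parametrize("res_code,atom_name,element,expected", [
    ("LYS", "NZ", "N", PolarityClass.POLAR),       # nonaromatic amino N
    ("GLY", "N", "N", PolarityClass.POLAR),
    ("SER", "OG", "O", PolarityClass.POLAR),
    ("HIS", "ND1", "N", PolarityClass.SPLIT),
    ("HIS", "NE2", "N", PolarityClass.SPLIT),
    ("TRP", "NE1", "N", PolarityClass.SPLIT),
    ("MET", "SD", "S", PolarityClass.HYDROPHOBIC),
    ("ALA", "CB", "C", PolarityClass.HYDROPHOBIC),
])
def test_amino_acid_polarity(res_code, atom_name, element, expected):
    res = make_residue(res_code, "A", 1, ResidueClass.AMINO_ACID,
                       [(atom_name, element, (0, 0, 0))])
    assert type_atom_polarity(res, res.atoms[0]) is expected


def test_modified_nucleotide_uses_parent_rules():
    res = make_residue("2MG", "B", 1, ResidueClass.MODIFIED_NUCLEOTIDE,
                       [("N9", "N", (0, 0, 0))], parent="G")
    assert type_atom_polarity(res, res.atoms[0]) is PolarityClass.HYDROPHOBIC


# --- blocking-carbon split ---------------------------------------------------

def _hexagonal_ring(radius=1.4):
    """Planar six-ring in the xy plane; first atom is a nitrogen."""
    atoms = []
    for k in range(6):
        ang = 2 * math.pi * k / 6
        el = "N" if k == 0 else "C"
        name = "N1" if k == 0 else f"C{k + 1}"
        atoms.append((name, el, (radius * math.cos(ang),
                                 radius * math.sin(ang), 0.0)))
    return atoms


def _ring_pocket():
    res = make_residue("RNG", "A", 1, ResidueClass.AMINO_ACID, _hexagonal_ring())
    from pocketdrug.structio import Pocket, Residue
    lig = make_residue("LIG", "L", 1, ResidueClass.LIGAND, [("C1", "C", (0, 0, 8))])
    from pocketdrug.structio import Pocket
    return Pocket(pocket_id="ring", receptor_atoms=res.atoms, ligand=lig), res


def test_split_conserves_total_sasa():
    pocket, res = _ring_pocket()
    atom = res.atoms[0]
    sasa_pol, sasa_hpb = split_aromatic_sasa(pocket, atom, res.atoms)
    from pocketdrug.surface import _atom_radii
    total = compute_sasa(
        np.array([a.position for a in pocket.receptor_atoms]),
        _atom_radii(pocket.receptor_atoms), probe=1.0,
        subset=np.array([0]),
    ).per_atom_area[0]
    # conservation is exact by construction: pol + hpb = total
    assert sasa_pol + sasa_hpb == pytest.approx(total, abs=1e-9)
    assert sasa_pol > 0 and sasa_hpb > 0


def test_split_fully_buried_atom_is_zero():
    from pocketdrug.surface import fibonacci_sphere

    cage = (fibonacci_sphere(60) * 4.0).tolist()
    ring = _hexagonal_ring(radius=1.0)
    res = make_residue("RNG", "A", 1, ResidueClass.AMINO_ACID, ring)
    lig = make_residue("LIG", "L", 1, ResidueClass.LIGAND, [("C1", "C", (0, 0, 0))])
    wall = make_point_pocket(cage, [[0, 0, 0]])
    from pocketdrug.structio import Pocket
    pocket = Pocket(pocket_id="buried", receptor_atoms=wall.receptor_atoms + res.atoms,
                    ligand=lig)
    sasa_pol, sasa_hpb = split_aromatic_sasa(pocket, res.atoms[0], res.atoms)
    assert sasa_pol == pytest.approx(0.0, abs=1e-9)
    assert sasa_hpb == pytest.approx(0.0, abs=1e-9)


def test_split_matches_monte_carlo_with_blockers():
    """sasa_pol equals a Monte-Carlo estimate with explicit blocker spheres."""
    pocket, res = _ring_pocket()
    atom = res.atoms[0]
    # dense lattice: the accessible patch is a few percent of the sphere
    sasa_pol, _ = split_aromatic_sasa(pocket, atom, res.atoms, n_points=20000)
    from pocketdrug.surface import _atom_radii
    pos = np.array([a.position for a in pocket.receptor_atoms])
    radii = _atom_radii(pocket.receptor_atoms)
    normal = np.array([0.0, 0.0, 1.0])
    blockers = np.array([atom.position + 1.70 * normal,
                         atom.position - 1.70 * normal])
    pos_b = np.vstack([pos, blockers])
    radii_b = np.concatenate([radii, [1.88, 1.88]])
    oracle = monte_carlo_sasa(pos_b, radii_b, probe=1.0, n_samples=2_000_000,
                              seed=3)[0]
    assert sasa_pol == pytest.approx(oracle, rel=0.01)


def test_split_degenerate_ring_rejected():
    res = make_residue("RNG", "A", 1, ResidueClass.AMINO_ACID,
                       [(f"C{k}", "C", (float(k), 0, 0)) for k in range(6)])
    lig = make_residue("LIG", "L", 1, ResidueClass.LIGAND, [("C1", "C", (9, 9, 9))])
    from pocketdrug.structio import Pocket
    pocket = Pocket(pocket_id="bad", receptor_atoms=res.atoms, ligand=lig)
    with pytest.raises(ValueError):
        split_aromatic_sasa(pocket, res.atoms[0], res.atoms)


# --- hydrophobic binding-site count ------------------------------------------

def test_all_carbon_pocket_counts_everything(cylinder_pocket):
    pocket, _ = cylinder_pocket
    sl = build_superligand(pocket, None)
    analysis = analyze_surface(pocket, sl)
    assert hydrophobic_bs_atom_count(analysis) == len(analysis.binding_site_records)


def test_all_polar_pocket_counts_nothing():
    from pocketdrug.fixtures import PocketSpec, synthetic_pocket

    pocket, _ = synthetic_pocket(PocketSpec(geometry="deep_cylinder",
                                            polarity_mix=1.0, n_wall_atoms=60,
                                            seed=2))
    sl = build_superligand(pocket, None)
    analysis = analyze_surface(pocket, sl)
    assert hydrophobic_bs_atom_count(analysis) == 0


def test_mixed_pocket_matches_bookkeeping_oracle():
    from pocketdrug.fixtures import PocketSpec, synthetic_pocket

    pocket, labels = synthetic_pocket(PocketSpec(geometry="deep_cylinder",
                                                 polarity_mix=0.4,
                                                 n_wall_atoms=60, seed=3))
    sl = build_superligand(pocket, None)
    analysis = analyze_surface(pocket, sl)
    expected = 0
    for rec in analysis.binding_site_records:
        cls = labels["polarity"][rec.atom.residue.seq_id]
        if cls == "hydrophobic":
            expected += 1   # hydrophobic atoms have fraction 1 (or element C)
    assert hydrophobic_bs_atom_count(analysis) == expected


def test_split_conservation_on_analysis(cylinder_pocket):
    pocket, _ = cylinder_pocket
    sl = build_superligand(pocket, None)
    analysis = analyze_surface(pocket, sl)
    for rec in analysis.records:
        assert rec.sasa_pol + rec.sasa_hpb == pytest.approx(rec.sasa_total, abs=1e-9)
        assert rec.sasa_pol >= 0 and rec.sasa_hpb >= -1e-12
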