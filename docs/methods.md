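# Methods

This note documents the models, numerical choices and known limitations of
`pocketdrug`, in the order the pipeline runs.

## Pocket model

A structure (mmCIF or PDB, read with gemmi) is reduced to a residue list
with a coarse classification: amino acid, nucleotide, modified nucleotide
(with a parent-code mapping), ligand, metal (monoatomic ions), water, or
other. Only the first model of multi-model files is used (the standard
convention for NMR ensembles). Alternate locations resolve to the
highest-occupancy copy, ties broken by file order. Hydrogens are retained
and flagged but ignored by every distance test and surface computation —
the ProtOr radius set is united-atom, with hydrogens folded into their
heavy atoms.

Carving keeps every residue with at least one heavy atom within the shell
radius (default 15 Å, boundary inclusive) of any ligand heavy atom. Waters
and metals are stripped; metals within 5 Å (inclusive, "not more than") of
the ligand come back one at a time as separate pocket variants so that the
effect of each ion can be assessed independently. Co-factor residues inside
the shell are treated as receptor. The dataset-assembly filter drops
structures whose ligands are all on an editable exclusion list of common
additives (glycerol, PEG fragments, sulfate, …) and keeps only the first
instance of a duplicated ligand code per structure.

## Superligand

The superligand is the pocket's negative print. Docked probe poses are
filtered by steric score per heavy atom (≤ −1.3, inclusive) and merged:
an atom survives only when confirmed by an atom of a *different* molecule
strictly within 1.2 Å, and mutually close atoms are deduplicated by a
greedy pass in a deterministic order (poses sorted by id, atoms in input
order), so the surviving points are pairwise ≥ 1.2 Å apart. A single pose
can never merge (no cross-molecule confirmation), and whenever no point
survives the crystallographic ligand's heavy atoms are used verbatim.
Superligand points are treated as aliphatic-carbon spheres (1.88 Å)
downstream.

Pose sources are pluggable: external multi-molecule SDF (score in an SD
tag) or the built-in rigid-body steric sampler. The sampler places each
probe conformer with uniform random rotations and translations inside the
reference ligand's bounding box inflated by 3 Å and scores a soft 6-12
Lennard-Jones with identical parameters for every receptor atom
(ε = 0.1 kcal/mol, r_min = 3.4 Å, per-pair energy capped at +10 kcal/mol,
8 Å cutoff) — the "all receptor atoms are uncharged carbons" convention of
steric-only docking. The default probe library is ~20 small rigid drug-like
molecules embedded with ETKDG at run time. The −1.3 cutoff is kept
numerically but its absolute meaning depends on the scoring function that
produced the poses; with the built-in sampler, sparse synthetic pockets
rarely reach it and the crystal-ligand fallback is the norm. The cutoff is
an explicit argument everywhere.

## Surface analysis

SASA is computed with an in-package Shrake–Rupley implementation: each
atom's probe-extended sphere is sampled on a deterministic Fibonacci
lattice (default 960 points, configurable) and a point is accessible if it
lies strictly inside no neighbouring extended sphere. Coincident equal
spheres bury all but the first (the union's area is counted once). Radii
come from an explicit ProtOr-class table keyed by element and atom-name
context; unknown types fall back to 1.80 Å with a warning. The probe is
1.0 Å. The engine is cross-checked in the tests against a Monte-Carlo
surface sampler and against biotite's independent implementation.

Binding-site atoms are receptor atoms whose SASA differs between the
superligand-bound and unbound states; the comparison tolerance is 1e−6 Ų
to absorb floating-point noise. Superligand points partition into surface
(SASA > 0 in the complex) and buried (SASA = 0) with the same tolerance.
Receptor SASA is computed on the carved shell, not the full structure —
consistent with carving being the unit of analysis, and a possible source
of small numerical differences versus whole-structure workflows.

Polarity classes: carbon, phosphorus and sulfur are hydrophobic everywhere,
as are the glycosidic base nitrogens (N9 of purines, N1 of pyrimidines);
amino-acid oxygens, ribose and phosphate oxygens and nonaromatic amino-acid
nitrogens are polar; endocyclic aromatic nitrogens of the bases and of
His/Trp side chains, and exocyclic base O/N, are ambivalent ("split").
A split atom's SASA is recomputed with two carbon spheres placed at
±1.70 Å along the least-squares ring normal (for exocyclic atoms, the
attached ring's plane): the remaining area is polar (in-plane
hydrogen-bonding), the blocked area hydrophobic (stacking). Both blockers
are present simultaneously; they occlude but contribute no area, so
sasa_pol + sasa_hpb = sasa_total exactly. Fully buried split atoms get
(0, 0). An atom counts as a hydrophobic binding-site atom when more than
half its SASA is hydrophobic; zero-SASA atoms fall back to their element
class (C/P/S hydrophobic). Metals occlude surface but are excluded from
polarity bookkeeping.

## Descriptors

The 12-descriptor vector:

| name | definition | units |
|---|---|---|
| `psa_r` | polar SASA of binding-site atoms / their total SASA (split atoms contribute their split parts) | fraction |
| `fr_hpb_atoms` | hydrophobic binding-site atom count / `no_bs_atoms` | fraction |
| `fr_buried_sl_atoms` | buried superligand points / all points | fraction |
| `hsa` | Σ hydrophobic SASA over binding-site atoms | Ų |
| `exp_sl_sa` | Σ SASA of surface superligand points in the complex | Ų |
| `sa_vol_r` | union-of-spheres (1.7 Å) surface area / volume of the superligand | Å⁻¹ |
| `no_bs_atoms`, `no_sl_atoms` | counts | — |
| `sl_bs_r` | `no_sl_atoms` / `no_bs_atoms` | ratio |
| `PMI3` | largest principal moment of inertia of the point set (unit masses) | Ų |
| `InertialShapeFactor` | I2/(I1·I3), 0 when I1 = 0 | — |
| `SpherocityIndex` | 3·λ_min/Σλ of the covariance eigenvalues, 0 for degenerate sets | — |

The exact algebraic forms of `psa_r`, `sl_bs_r`, `sa_vol_r` and `exp_sl_sa`
were fixed here from the descriptor names and the documented directionality
(druggable pockets are less polar, more enclosed, less solvent-exposed);
each is unit-tested for that directionality on contrasting fixtures. An
alternative burial-area definition of `sl_bs_r` was considered and the
count ratio chosen for robustness; the surface module exposes everything
needed to compute variants. The union-of-spheres volume uses voxel-centre
counting on a 0.3 Å grid; the area is the zero-probe Shrake–Rupley area,
so for a single sphere `sa_vol_r → 3/r` as the grid refines (verified at
0.3/0.15 Å). Shape terms use unit masses about the centroid; degenerate
sets (≤ 2 points, collinear points) map to 0 explicitly. The remaining
descriptors a full 23-descriptor screen would include are left as an
extension point: the model accepts any descriptor subset by name.

## Classifier

XGBoost with a binary-logistic objective (probability output). Diverging
from library defaults only where documented: `max_depth=3`,
`scale_pos_weight=0.63` (training-set class skew), early stopping with
patience 20 monitored on the validation logloss (the library's default
metric — none is prescribed), round cap 1000, single-threaded with an
explicit seed for bit-reproducibility. Scores ≥ 0.5 (boundary inclusive)
are labelled druggable. Metrics are accuracy plus per-class precision and
recall pairs; zero-denominator cases are reported as undefined, never as 0.

SHAP values come from XGBoost's native TreeSHAP
(`predict(pred_contribs=True)`); the per-descriptor mean |SHAP| over a
table is the importance ranking, and additivity (contributions + base =
margin) is asserted in the tests. Descriptor elimination retrains after
dropping the weakest descriptor and stops as soon as validation accuracy
falls strictly below the best seen, returning the model fitted just before
the degrading step. In leave-one-out cross-validation each fold trains with
the training fold itself as the early-stopping eval set, since no held-out
validation data exists inside a fold.

## Families and consensus

Sequences are aligned globally with Biopython's `PairwiseAligner` using
identity scoring (match 1, mismatch 0, gap 0); similarity is
matches / alignment length × 100. An infinitesimal gap penalty (1e−6)
breaks score ties toward gap-free alignments, which a literal zero penalty
would pad arbitrarily. The alignment scoring is configurable — it is the
least-determined part of the family definition. Binding-site sequences
list the residues contributing at least one binding-site atom in ascending
(chain, number) order, with modified nucleotides mapped to their parent
codes. Families are the single-linkage transitive closure over pairs with
similarity strictly above the cutoff (98 % overall-sequence, 85 %
binding-site). Consensus is C = |n_d − n_ld|/N × 100, the unique linear
form matching its two defining anchors (100 % unanimous, 0 % even split).

## Ligand properties

QED uses RDKit with average (mean) descriptor weights; classes are
drug-like (≥ 0.67), less drug-like (≤ 0.49), moderate in between, both
boundaries inclusive. Ligand efficiency is −RT·ln(K_d)/N_heavy with
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ at 298.15 K (RT ≈ 0.5925 kcal/mol); the
temperature is not part of the published K_d values, and 298.15 K
reproduces the checkable linezolid row (0.27 at K_d = 20,000 nM,
24 heavy atoms). K_d ≥ 1 M gives LE floored at 0 with a warning. clogP is
the standard atom-contribution estimate and implementation-defined to
roughly ±0.5.

## Synthetic data

The fixture generator builds pockets from single-atom pseudo-residues with
real residue codes (glycine CA-like carbons, glycine backbone-O-like
oxygens) so the polarity rules fire naturally, on four geometries at
~3.5 Å wall spacing: deep cylinder, shallow groove, closed cage, open
plane, each with a small carbon ligand at the cavity centroid. Analytic
labels record each wall atom's polarity and whether it lies within
occlusion reach of the ligand, giving an independent expectation for the
binding-site set. These fixtures exercise the geometry and bookkeeping of
the pipeline but deliberately do not mimic real RNA folds, base stacking,
backbone connectivity or crystallographic noise — passing tests demonstrate
correctness of the computations, not predictive accuracy on real pockets.

Labelled descriptor tables carry the druggability signal in `psa_r` (low
for druggable), `fr_buried_sl_atoms` and `hsa` (high for druggable), with a
mean shift of 0.15·effect (effect 1.0, noise SD 0.1 by default — enough
overlap to be non-trivial while learnable at n = 200) and all other
descriptors as uninformative noise within their type ranges. Property
checks run at n = 200 rows and 20 seeds, sizes at which the recovery and
elimination behaviour is stable.

## Determinism and numerical notes

Every stochastic component (sampler, fixtures, training) takes an explicit
seed; training is single-threaded. The Fibonacci lattice makes SASA exactly
reproducible but introduces an orientation-dependent discretisation error
of order 1 % at 960 points — rigid-motion invariance tests therefore use a
small tolerance, and high-precision comparisons (the blocking-carbon
oracle) use denser lattices. ΔSASA thresholds use a 1e−6 Ų tolerance.
Degenerate inputs fail loudly: empty pose lists, empty families, collinear
rings, single-class training tables and pockets without binding-site atoms
all raise rather than return defaults.

## Limitations

* The built-in steric sampler is a stand-in for a full docking engine: it
  is rigid-body, steric-only and coarsely sampled, so its score scale is
  not comparable to grid-based docking scores even though the same
  score-per-heavy-atom filter is applied.
* Published benchmark quantities that require bulk PDB retrieval and
  docking campaigns (training/test accuracies on the protein benchmark,
  druggable fractions of RNA/ribosome survey sets, family tables) are out
  of desk scope; the corresponding machinery is validated by construction
  on fixtures and against independent oracles instead.
* The ProtOr radius assignment covers standard residues and common atom
  names; exotic chemistry falls back to a generic 1.80 Å radius.
* Overall-sequence family grouping compares single chains; multi-chain
  entries use the best-matching chain pair.
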