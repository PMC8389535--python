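# pocketdrug

Structure-based druggability prediction for RNA, protein and mixed binding
sites.

Most druggability predictors were built for proteins and lean on amino-acid
specific descriptors, which makes them useless for the growing class of RNA
drug targets (riboswitches, ribosomal sites). `pocketdrug` implements a
receptor-agnostic pipeline: it characterises a binding site purely through
its geometry and the polarity of its solvent-accessible surface, so the same
model applies to protein, RNA and mixed pockets. It is aimed at structural
bioinformaticians and medicinal chemists triaging candidate binding sites.

## Method

1. **Pocket carving** — all residues with an atom within 15 Å of the bound
   ligand form the binding-site shell; metal ions within 5 Å of the ligand
   yield separate single-metal pocket variants.
2. **Superligand** — a negative print of the pocket, built by merging heavy
   atoms of sterically docked probe molecules. Poses with a van-der-Waals
   score per heavy atom ≤ −1.3 are kept; an atom survives the merge only if
   an atom from a *different* molecule lies closer than 1.2 Å, deduplicated
   so surviving points are ≥ 1.2 Å apart. If nothing survives, the
   crystallographic ligand is the superligand. Poses come from any external
   docking program or the built-in rigid-body steric sampler (soft
   Lennard-Jones, every receptor atom treated as an uncharged carbon).
3. **Surface analysis** — Shrake–Rupley SASA with ProtOr united-atom radii
   and a 1.0 Å probe. Receptor atoms whose SASA changes when the
   superligand is present are *binding-site atoms*; superligand points with
   zero SASA in the complex are *buried*. Atom polarity: C/P/S and the
   glycosidic base nitrogens are hydrophobic; amino-acid, ribose and
   phosphate oxygens and nonaromatic amino-acid nitrogens are polar;
   ambivalent aromatic atoms (endocyclic base/His/Trp nitrogens, exocyclic
   base O/N) have their SASA split into polar (in-plane) and hydrophobic
   (stacking) parts by two blocking carbons placed 1.70 Å along the ring
   normal.
4. **Descriptors** — a 12-component vector: relative polar surface area
   `psa_r`, hydrophobic-atom fraction `fr_hpb_atoms`, hydrophobic surface
   `hsa`, buried-superligand fraction `fr_buried_sl_atoms`, exposed
   superligand surface `exp_sl_sa`, surface/volume ratio `sa_vol_r`, counts
   `no_bs_atoms` / `no_sl_atoms` and their ratio `sl_bs_r`, and the shape
   terms `PMI3`, `SpherocityIndex`, `InertialShapeFactor`.
5. **Classifier** — an XGBoost ensemble (binary logistic objective,
   `max_depth=3`, `scale_pos_weight=0.63`, early stopping with patience 20);
   score ≥ 0.5 ⇒ druggable. TreeSHAP values rank descriptors and drive
   iterative elimination of the weakest ones.
6. **Families & consensus** — pockets are clustered by global pairwise
   sequence alignment (identity scoring; cutoffs >98 % overall, >85 %
   binding-site) with single linkage, and each family's prediction
   consensus is C = |n_d − n_ld|/N × 100.

Ligand characterisation (QED with average weights, classed drug-like at
≥ 0.67 and less drug-like at ≤ 0.49, plus ligand efficiency
LE = −RT·ln(K_d)/N_heavy) rounds out the toolkit.

## Worked example

```bash
python examples/characterize_ligand.py
```

```
linezolid: QED = 0.89 (drug_like)
ligand efficiency = 0.27 kcal/mol per heavy atom
```

QED 0.89 means linezolid scores highly on the composite drug-likeness
desirability scale (≥ 0.67 is drug-like); an LE of 0.27 kcal/mol per heavy
atom is just below the conventional ~0.3 hit-quality bar.

```bash
python examples/train_and_rank.py
```

```
validation accuracy (12 descriptors): 1.00
top descriptors by mean |SHAP|:
    fr_buried_sl_atoms  1.884
                 psa_r  1.695
                   hsa  1.402
after elimination: 3 descriptors kept: ['psa_r', 'fr_buried_sl_atoms', 'hsa']
```

On a synthetic table whose druggable pockets were generated with low polar
surface area and a deeply buried superligand, the model recovers exactly
those descriptors as the top SHAP contributors and elimination prunes the
noise columns.

Other examples: `examples/pocket_descriptors.py` (descriptor vectors for a
deep apolar vs a shallow polar pocket) and `examples/family_consensus.py`
(family clustering and consensus scores). The same functionality is
available from the shell via the `pocketdrug` command (`carve`,
`superligand`, `surface`, `describe`, `train`, `predict`, `families`,
`ligprops`, `fixtures`, `run`).

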