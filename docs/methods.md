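# Methods

## Scope and model

`fieldsar` analyzes a congeneric ligand series whose 3D poses share one
receptor coordinate frame (the usual situation after docking a series
into a single rigid receptor).  Four stages build on that shared frame:

1. **Pose similarity.**  For a probe and a reference molecule, the
   maximum connected common subgraph over heavy atoms is found and the
   RMSD is evaluated in place — no superposition — because any fitting
   step would erase exactly the information of interest (whether the
   common fragment *docked* to the same place).  Two coverage numbers
   accompany each RMSD: %RefMatch (common-graph size over the
   reference's heavy atoms) and %MolMatch (over the probe's).  A small
   RMSD at low coverage is not evidence of a conserved binding mode.
2. **Pose filtering.**  Congeneric series usually have one or more
   interactions that every plausible pose must satisfy (here: the
   protonated amine within salt-bridge distance of a glutamate
   carboxylate).  Among poses passing all such predicates the
   best-scored one is kept; if none passes, the overall best scorer is
   kept but flagged, so no compound silently drops out of the series.
3. **Interaction fingerprints.**  Per residue and complex, boolean
   chemotype bits (C, B, S, P, H, A, D, Ar, Ch) with a strict implication
   hierarchy: any chemotype implies a contact; an H-bond implies a polar
   contact.  Occurrence profiles aggregate bits over the series as
   percentages, which is how conserved anchors (100% charged contact at
   the glutamate) are read off.
4. **3D-QSAR.**  Steric (Lennard-Jones) and electrostatic (Coulomb)
   probe energies on a rectilinear grid form the descriptor matrix;
   after pretreatment and block scaling, PLS links fields to pKi.

## Field engine

* Grid: spacing 1.0 Å, padding 5.0 Å around the union of all atoms
  (axis count = floor(range/spacing)+1).
* Steric probe: sp³ carbon.  E = Σ ε_pair[(Rmin/r)¹² − 2(Rmin/r)⁶] with
  Rmin_pair = Rmin_i/2 + Rmin_probe/2 and ε_pair = √(ε_i ε_probe).  The
  per-element (Rmin/2, ε) table is pinned in `fields.VDW_PARAMS`
  (conventional organic-element magnitudes, e.g. C: 1.95 Å, 0.070
  kcal/mol); the exact vdW parameterization is a documented choice, and
  correctness is asserted through closed-form properties (the pair
  minimum equals −ε_pair at Rmin) rather than bit-agreement with any
  particular force-field release.
* Electrostatic probe: charge +1 e, E = Σ 332.0637·q_i/(ε(r)·r) with the
  distance-dependent dielectric ε(r) = r (a standard implicit-screening
  choice for protein-frame calculations); energies in kcal/mol.
* Pretreatment: values above +30 kcal/mol are capped at +30; the
  electrostatic block is also floored at −30 (the steric block has a
  physical minimum near −ε and needs no floor); |E| < 0.05 kcal/mol is
  zeroed; variables with ≤ 4 distinct values across compounds (n-level)
  or zero variance are removed from modeling.  Buried nodes are
  evaluated then capped, not masked.
* BUW (Block Unscaled Weighting): each field block is multiplied by
  1/√(total column variance of the block), giving every block unit total
  variance while preserving intra-block ratios.  Variances use ddof = 1.
* SRD (Smart Region Definition): per block, the n_seeds alive variables
  with the largest preliminary-PLS |coefficient| seed regions (default
  n_seeds = 10% of alive variables, capped at 200); alive variables
  within 2.0 Å of a seed join the nearest seed; adjacent regions (closest
  nodes within 1.5× grid spacing) whose mean compound profiles correlate
  ≥ 0.8 in absolute value are merged; unassigned variables are dropped.
  Ties break toward the lowest variable index, so the grouping is
  deterministic.  The pipeline stops at grouping plus orphan-dropping;
  no factorial variable selection is layered on top.

## PLS and statistics

NIPALS PLS1 with mean-centering of X and y and no per-variable scaling
(BUW already fixed the block variances).  Regression coefficients are
B = W(PᵀW)⁻¹q.  Conventions:

* R² = 1 − SSres/SStot; fitting S = √(SSres/(n − NC − 1)) — the
  denominator convention is stated here because several are in use.
* LOO: each fold refits (re-centering included) but the alive-variable
  set and BUW weights are frozen from the full training matrix.
  Refitting the pretreatment per fold is stricter but makes fold models
  live on different variable sets; the frozen variant is the common
  practice this package follows.  Q² = 1 − PRESS/Σ(y−ȳ)², S_LOO =
  √(PRESS/n).
* External: Rtest² is the squared Pearson correlation between predicted
  and observed (the packaged published table confirms this convention
  numerically: the predictive variant 1 − PRESS/SS gives 0.60 where the
  printed value is 0.61); S_test = √(SSE/n_test).
* Field contributions: component a explains q_a²·(t_aᵀt_a) of the
  response sum of squares; that share is split across blocks by the
  squared x-weights (unit norm per component) and normalized to sum
  to 1.  Duplicated identical blocks split 50/50 by symmetry.
* Model selection scans {steric}, {electrostatic}, {both} × NC 1–8 and
  keeps the highest Q²; ties break toward fewer components, then fewer
  fields.  The scan ceiling of 8 components follows the largest model
  actually reported for series of this size; LOO (not fit) decides, so
  the extra headroom cannot inflate the selected model.
* Contours: per field, coefficient × column SD at each node (dead
  variables are 0); iso-levels default to ± the 85th percentile of the
  nonzero absolute values — a display choice, not a statistic.

## Synthetic data: what it emulates, what it does not

The generator emulates the *statistical* structure the analysis assumes:
a fixed scaffold in one frame (pharmacophore-style: protonated amine
between a large and a small hydrophobic group), substituents with
idealized template geometry at two attachment points, and activities
that are exactly linear in field occupancy of planted spherical regions
(+ Gaussian noise in pKi, default SD 0.3; the recovery experiments use
0.2).  Default series size is 40 compounds with a stratified 8-compound
external split — a desk-scale stand-in for the published 80/16 series.
Partial charges are simple fixed template values around the ammonium and
polar substituents.

It does **not** emulate conformational flexibility, docking-score noise,
pose misalignment, protonation equilibria, or realistic charge
distributions.  Passing the recovery tests therefore shows the pipeline
recovers a linear field-occupancy signal planted under its own
assumptions — a correctness statement about the machinery, not evidence
that any real series satisfies those assumptions.

The toy pocket places a glutamate carboxylate ~3.2 Å above the ammonium
along the N–H vector, a leucine by the R1 substituent zone and a
phenylalanine ring stacked 3.8 Å over the scaffold benzene, so
salt-bridge detection, H-bond geometry, hydrophobic and aromatic bits
all have positive controls by construction.

## Numerical and degenerate-input choices

* MCS search is exhaustive branch-and-bound with a node budget
  (default 2·10⁶ states); within budget the result is exact and, among
  maximum-size mappings, the one with the smallest in-place RMSD is
  returned (poses share a frame, so this tie-break is well defined).
  Atom compatibility = same element + aromaticity + ring membership,
  with equal smallest-ring size unless `ring_relaxed`; bonds match on
  equal order.  Deterministic atom ordering makes results reproducible.
* Hydrogen-bond bits apply the ≥ 120° donor-angle test only when
  explicit hydrogen coordinates exist (synthetic ligands carry the
  ammonium H); otherwise the heavy-atom distance decides — receptors
  stripped of hydrogens are the norm.
* A residue with missing side-chain atoms loads with a warning and
  leaves side-chain-dependent bits unset; alternate locations keep the
  highest-occupancy conformer.
* Constant y, empty pose lists, empty grids, zero-variance blocks and
  out-of-range component counts raise errors rather than degrade.
* PLS component extraction stops early if the residual response is
  exhausted; a candidate whose effective NC collapsed below the request
  is discarded during the scan (it duplicates the smaller model).
* Racemic input is out of the package's hands by design: each supplied
  pose is its own record, and enantiomer selection is the caller's
  responsibility via the activity table.
* The stratified split sorts by pKi, cuts into n_test equal-rank bins
  and draws one test compound per bin with the seeded generator, so both
  subsets span the activity range.

## Problem sizes used by tests and the acceptance script

Published-table statistics are exact recomputations (n = 80).  The PLS
reference comparison uses 50 random problems (8–15 rows, 5–29 columns).
MCS brute-force cross-checks use random molecules of 4–10 heavy atoms.
The recovery experiment uses 40 compounds on a ~1 Å grid (≈13 000 raw
variables before pretreatment); the noise control averages 10 seeds.

## Known limitations

* Steric/electrostatic probes only — no hydrophobic, H-bond or
  desolvation fields.
* The vdW parameter table covers common organic elements (H, C, N, O,
  F, P, S, Cl, Br, I); exotic elements raise an error.
* Rtest² as squared Pearson correlation rewards correlation even with
  systematic bias; S_test should always be read alongside it.
* The MCS node budget can, for highly symmetric molecules beyond the
  tested sizes, return a best-found rather than provably maximal
  mapping (deterministically so).
* Interaction-fingerprint cutoffs are conventional defaults, not fitted
  to any receptor family; occurrence percentages shift with the
  cutoffs, which is why they are all configurable.
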