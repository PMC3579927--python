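# Methods

This note documents the models implemented in `vsbench`, the defaults and
numerical choices, what the synthetic-data generators emulate, and the
limitations a user should keep in mind.

## Decoy selection

**Model.** Decoys calibrate docking enrichment: they should mimic the
actives' physicochemical profile (so trivial property differences cannot
separate them) while being distinct structures. Each candidate is scored
against an active by

```
decoy_score = ΔPK + |comboscore − 2|
```

`ΔPK` sums the absolute differences of seven descriptors — H-bond acceptor
count, H-bond donor count, logS (log10 mol/L), SlogP, molecular weight
(Da), rotatable-bond count, TPSA (Å²). The comboscore ∈ [0, 2] is a 3D
similarity (2 = identical), so `|comboscore − 2|` is its complement; both
terms are "smaller = better mimic" and are summed without weighting.

**Selection.** Actives are processed in pool order (configurable). For each
active all *remaining* candidates are scored, ranked ascending (ties broken
lexicographically by candidate id for determinism) and the top `quota`
(default 20) are selected and removed from the pool. Removal makes the
per-active decoy sets disjoint by construction and makes the output depend
on the active processing order; the order used is recorded in the result.

**ΔPK modes.** The descriptors have incommensurate units, and the default
`raw` mode sums them anyway — molecular weight (hundreds of Da) therefore
dominates in practice. This literal unweighted sum is the primary
definition; a `scaled` mode dividing each term by a user-supplied scale
(e.g. `mad_scales`, per-descriptor median absolute deviation over the pool)
is provided for users who want unit-free balancing. Both are exposed on the
CLI; nothing in the selection algorithm depends on the choice.

**Descriptor provenance.** logS and SlogP are model-dependent, so all seven
descriptors come through a pluggable provider, never computed ad hoc inside
the algorithms. The RDKit-backed provider uses Lipinski acceptor/donor
counts, Crippen SlogP, `CalcTPSA`, and the ESOL (Delaney 2004) regression
for logS; the choice is recorded in provider metadata. Descriptor tables
can also be read directly from CSV, in which case whatever program produced
them defines the descriptor variants.

## Comboscore (USR-style reference provider)

The original-style comboscore comes from proprietary overlay software whose
numeric values cannot be reproduced; decoy selection only consumes a scalar
in [0, 2], so the provider interface *is* the contract. The bundled
reference provider is alignment-free, in the ultrafast-shape-recognition
(USR) tradition:

* **Shape term.** For four reference points — centroid, atom closest to the
  centroid, atom farthest from the centroid, atom farthest from that atom —
  take the distance distribution to all atoms and record its mean,
  population SD, and the signed cube root of its third central moment
  (cube-rooting keeps units in Å, the classic 12-descriptor construction).
  Tied reference-point selections resolve to the lowest atom index.
  Similarity between two moment vectors is `1/(1 + L1/12)` ∈ (0, 1], a
  standard inverse-translated Manhattan kernel; it equals 1 iff the moments
  are identical and is invariant to rigid motion of either conformer.
* **Color term.** The same moments restricted to atoms of each
  pharmacophore feature type (donor, acceptor, anion, cation, aromatic,
  hydrophobe); the term is the mean, over types present in either molecule,
  of the per-type similarity, with 0 for a type present in only one. For
  identical tagged clouds the color term is 1 and the total is 2.

The provider is single-conformer (each record's stored geometry is used
as-is) and caches moments by molecule id. No pose overlay or Gaussian
volume optimisation is attempted, and the values are *not* expected to
match any particular overlay program — only to rank similar structures
high, which is all the selection consumes. A `table` provider reads
precomputed pairwise comboscores from CSV for users with access to an
external program.

## Enrichment and consensus

* **Ensemble aggregation:** per-ligand *best* (minimum) score over the
  selected receptor models, the usual keep-best-pose convention; `mean` is
  available as a config hook.
* **Recovery curve:** ligands ranked ascending by score; tied scores
  receive average ranks so the curve does not depend on input order. The
  curve starts at (0, 0), has a point after each rank position, and ends at
  (1, 1).
* **Truncated AUC:** trapezoidal area over [0, x] of the piecewise-linear
  curve, by default *unnormalized* — for n actives of N ligands a random
  ranking gives ≈ x²/2 and the perfect ranking gives
  `n/(2N) + (x − n/N)` (for x ≥ n/N), so at x = 0.1 with 11/231 the
  perfect score is ≈ 0.076 and chance is 0.005. `normalize="ideal"`
  divides by the perfect-ranking area, mapping onto [0, 1]. The raw
  default is the scale on which per-model early-recognition AUCs in the
  0.05–0.065 range arise for strongly enriched 231-ligand screens.
* **Duplicate-state averaging:** docking scores of ionization states /
  tautomers of the same parent are arithmetically averaged per parent.
* **Consensus:** mean of the two rank positions (Borda), the
  minimal-assumption combination rule when two programs' score scales are
  incomparable; final ties break lexicographically by ligand id.

## Conformer clustering

Frames are superposed onto the first frame (Kabsch, via SciPy's
`Rotation.align_vectors`, always a proper rotation; degenerate/collinear
point sets are rejected) to remove rigid-body motion; pairwise RMSD is then
computed directly on a caller-supplied atom mask without per-pair refitting,
matching the superpose-then-cluster trajectory protocol. The mask recipe
"residues within 10 Å of the binding pocket" is provided as a helper
(`atoms_near`: minimum-distance shell, default 10 Å, heavy atoms by default)
rather than baked in, so the module is not bound to one structure format's
residue model.

gromos clustering: repeatedly, the unassigned frame with the most
unassigned neighbours within the cutoff (default protocol value 0.75 Å)
becomes a centroid; it and its neighbours form a cluster and are removed.
Neighbour-count ties go to the lowest frame index — deterministic and
consistent with common implementations. Centroids of the top-k most
populated clusters (default 5) are selected for docking; a frame chosen on
other grounds (e.g. solvent-accessible-surface-area arguments, which this
package does not compute) can be appended explicitly.

## Kinetics

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`),
with IC50, Km, Ki and αKi parameterised as base-10 logs to enforce
positivity; natural-scale standard errors are obtained by the delta method.
Initial values come from the data: plateaus from the response extremes,
IC50 from the concentration nearest the half-range response, Km from the
substrate concentration nearest half-maximal rate at the lowest inhibitor
level. Zero concentrations are dropped from dose–response fits (the model
lives on log X); S = 0 rows are dropped from kinetic fits. The Hill slope
is fit freely by default (`fixed_1` pins it), since both variants are
standard in plate-reader analysis software; the choice is recorded in the
fit object.

The uncompetitive model is the primary kinetic model. Because allosteric
small-molecule inhibitors are often described as non-competitive while
being *fitted* with an uncompetitive equation, a mixed-inhibition variant
(free Ki and αKi, nesting both mechanisms) is provided so users can compare
fits rather than assume a mechanism; the package does not adjudicate.

## Synthetic data

The generators are first-class, tested code: each is a pure function of its
spec and seed (one `numpy` Generator stream per call), and each plants a
known structure whose recovery by the matching pipeline stage is asserted
in the test suite.

* **Pools** (`gen_pool`): defaults of 11 actives and 500 candidates match
  the validation-screen geometry (11 actives × 20 decoys = 220 from a pool
  comfortably larger). Descriptors are drawn from drug-like windows (MW
  150–550 Da, TPSA 20–140 Å², SlogP −1–6, logS −6–−1, counts 0–10/0–5/0–10
  for acceptors/donors/rotatable bonds); atom clouds of 10–30 points with
  feature types drawn hydrophobe-heavy (0.40/0.20/0.15/0.15/0.05/0.05 for
  hydrophobe/aromatic/donor/acceptor/cation/anion). A `mimic_fraction`
  (default 0.3) of candidates are perturbed copies of randomly chosen
  actives — counts nudged ±1, continuous descriptors jittered by 2% of
  their window, atom clouds jittered by 0.3 Å with tags kept — so they
  carry small ΔPK and comboscore near 2 against their source active.
* **Screens** (`gen_screen`): 231 ligands (11 actives + 220 decoys) × 7
  models by default. Ligands draw a base score from class-specific normals
  (defaults: actives N(−9, 1), decoys N(−6.5, 1), kcal/mol-like,
  lower = better — a strong-enrichment scenario of 2.5 SD separation) and
  each model column adds N(0, 0.5) jitter. An optional duplicate-variant
  table (e.g. 115 parents) feeds the averaging step.
* **Conformers** (`gen_conformers`): blob references differ by *per-atom*
  displacements of RMS magnitude `separation` (default 5 Å) — genuine
  conformational change, deliberately not rigid-body offsets, which the
  superposition step would cancel. Frames add isotropic jitter (default
  0.2 Å); blob populations default to distinct descending sizes so the
  top-k centroid selection is unambiguous.
* **Kinetics** (`simulate_kinetics` / `simulate_dose_response`): model mean
  plus Gaussian noise. The Monte-Carlo recovery studies use truth values
  IC50 = 1.1 µM (Top 100, Bottom 0, Hill 1) and Vmax = 100 RFU/min,
  Km = 50 µM, αKi = 0.69 µM, with noise SD 3% of the maximal rate. The
  dose–response design is a plate-style 2-fold serial dilution from 500 µM
  (16 steps, reaching 15 nM, i.e. the 10 nM–500 µM titration window) in
  duplicate — with a sparse single-replicate 8-point design the IC50's
  Cramér–Rao bound alone is ~7% relative SE at this noise, so the design,
  not the estimator, controls achievable recovery. The kinetic design is
  S ∈ {10, 25, 50, 100, 200} µM × I ∈ {0, 0.5, 1, 2} µM.

**What the generators do not emulate:** real chemistry (synthetic records
have no SMILES; descriptors are sampled, not computed from structure),
correlated descriptors (real MW and TPSA are correlated; samples are
independent), docking-score physics (normal score distributions stand in
for whatever a docking function produces), heteroscedastic assay noise, or
anharmonic trajectory motion. Passing tests therefore demonstrate that the
*algorithms* recover planted structure under clean statistical conditions —
not that any particular docking engine or assay will show the same
separation.

## Numerical choices and degenerate inputs

* Decoy-score and centroid ties: lexicographic / lowest-index, so all
  outputs are deterministic.
* RMSD matrices are symmetrised (`(M + Mᵀ)/2`) against floating-point
  round-off before clustering; gromos validates symmetry to 1e-8.
* Kabsch rejects < 3 points and collinear geometries (rank < 2 after
  centering, tolerance 1e-8 relative).
* `shape_moments` of a single atom is the zero vector; skew uses the
  *population* third central moment.
* Recovery curves require at least one active and one decoy; truncated AUC
  requires 0 < x ≤ 1 and interpolates the partial trapezoid at x exactly.
* Malformed pool entries are skipped with a logged warning and count;
  duplicate ids abort.

## Problem sizes

Validation runs use the study-scale geometries throughout: 500-candidate
pools for selection, 231 × 7 score tables for enrichment (500 replicates
for the null calibration), 60-frame ensembles for clustering, 100 seeded
trials per brute-force oracle comparison, and 200 Monte-Carlo replicates
per kinetic recovery study. The full suite runs in well under a minute on
one CPU.

## Known limitations

* The reference comboscore is not ROCS and will not reproduce overlay-based
  values; use the `table` provider to inject external similarities.
* `raw` ΔPK is dominated by molecular weight; use `scaled` when that is not
  intended.
* Decoy assignments depend on the active processing order (inherent to
  iterative removal); the order is recorded, not optimised.
* The gromos implementation is O(n²) in frames via the full RMSD matrix —
  fine for hundreds of frames, not for full MD trajectories at 1 ps
  sampling without prior thinning.
* Homology modelling, MD simulation, docking, SASA, and PROCHECK internals
  are out of scope; `model_quality` only does the summary arithmetic over
  an externally produced Ramachandran distribution.
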