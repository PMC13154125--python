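# Methods

This note records the scientific conventions, default parameters and design
choices behind `xtalgroup`, and what the synthetic-data tests do and do not
demonstrate about real crystallographic data.

## Problem setting

Organic molecules crystallize into the 230 space groups with a famously
uneven frequency distribution; a handful of groups (P2₁/c, P‑1, P2₁2₁2₁,
C2/c, P2₁) account for most structures. Treating space-group assignment as a
multiclass problem, a useful model must beat the *frequency reference* —
always predicting the N most frequent groups — not merely random guessing.
All evaluation in this package is therefore top-N against explicit baselines.

Enantiopure chiral molecules can only crystallize in the 65 Sohncke groups
(proper operations only); this constraint is enforced as a hard rule both in
the label generator and as a shipped static table (`_sohncke.py`).

## Dataset curation

Polymorph families (one molecule, several structures) are collapsed either to
the first-deposited record (`first_polymorph_only`, realized by an explicit
`deposition_rank`) or to one record per distinct space group
(`unique_space_group_polymorphs`). Balanced subsets keep the `k` most
frequent labels (frequency ties broken toward the lower space-group number,
for determinism) and subsample every kept label to the size of the rarest
one, so the label histogram is exactly uniform.

Splits use seeded shuffling with largest-remainder rounding; stratified
splits apply the rounding per label, so per-label counts deviate from the
exact proportion by less than one record. Strata with fewer than three
records go entirely to training (with a warning) rather than producing empty
validation/test cells. Largest-remainder rounding is this package's choice;
other roundings would differ only at the single-record level.

## Point-group census

`detect_symmetry` counts every operation individually (C₃ and C₃² are two
operations), so the total equals the group order for non-linear molecules —
the reading of "number of symmetry operations" that matches group theory.
Per-class counts (E, C₂…C₈, σ, i, S₃…S₈) are exposed alongside the total so
either convention (operations or classes) can be recovered downstream.

Key choices:

* **Tolerance.** An operation is accepted if it maps the element-labeled
  point set onto itself with maximum displacement ≤ tolerance (optimal
  per-element matching via the Hungarian algorithm). Default 0.05 Å for
  relaxed geometries; 0.1 Å is the documented looser setting for geometries
  taken from crystal structures.
* **Candidate generation.** Any symmetry axis or mirror normal must be an
  eigenvector of the inertia tensor. With non-degenerate principal moments
  only the three principal axes are candidates; under degeneracy (relative
  moment gap < 0.05) atom vectors, pair sums (C₂ bisectors) and pair
  differences (mirror normals for atom-swapping reflections) are added.
  Proper/improper rotation orders are enumerated up to n_max = 8 — organic
  molecules essentially never exceed C₈. Axes through ring centroids that
  contain no atom and are not principal axes (fullerene-like cases) are
  outside this enumeration.
* **Identification.** Each accepted operation is keyed by the atom
  permutation it induces together with its determinant sign; for non-linear
  molecules this pair identifies the operation uniquely (two operations with
  the same key would compose to a nontrivial rotation fixing every atom).
  The canonical matrix for classification comes from det-constrained Kabsch
  superposition onto the permuted coordinates.
* **Masses.** Centering uses standard atomic weights; matching uses element
  identity only — the conventional point-group assignment.
* **Linear molecules** have a continuous axis; their census is computed
  analytically with rotation orders capped at n_max and the report flagged
  `linear`. The brute-force oracle used in tests cannot terminate on linear
  input, so oracle-equivalence checks cover non-linear geometries, and the
  linear fixture is tested against the capped contract instead.

## Shape and chemical descriptors

NPR1 = I₁/I₃ and NPR2 = I₂/I₃ come from the mass-weighted inertia tensor
(standard atomic weights), as does eccentricity √(I₃²−I₁²)/I₃. Asphericity
follows the gyration-tensor convention of the mainstream cheminformatics
descriptor library: 0.5·Σᵢ<ⱼ(eᵢ−eⱼ)² / (Σe)² over mass-weighted gyration
eigenvalues, giving 0 for a spherical top and 1 for a perfect rod. All four
are cross-checked in the tests against the independent RDKit 3D descriptor
implementations to 10⁻⁶. Planarity is the mean absolute atomic distance from
the unweighted least-squares plane (normal = smallest principal direction of
the centered second-moment matrix); for isotropic second moments the
smallest-index eigendirection is chosen deterministically and the value
flagged.

Chemical features are counts of 18 functional groups from a versioned,
human-readable SMARTS file (`data/functional_groups.smarts`). Patterns are
mutually disambiguated: ester oxygens are not ethers, carboxylic acids are
not esters, anhydrides are not esters, amide nitrogens are not amines,
thiols are not thioethers. "Halide" counts halogen *atoms* bonded to carbon
(CF₃ counts 3). Hydroxyl counts include phenols. TPSA uses the Ertl
atom-contribution method via RDKit.

Feature selection drops columns with variance < 10⁻⁸, then for each pair
with |Pearson r| > 0.9 drops the later column in the fixed schema order.
The fitted retained-column list can be re-applied verbatim to another table
(e.g. fit on a balanced subset, apply to the unbalanced set). Both
thresholds are exposed on the CLI; the defaults are this package's choice.

## Graph track

Graphs carry explicit hydrogens by default — hydrogen bonding is central to
packing preferences — with a documented heavy-atom switch (implicit-hydrogen
Gasteiger charge folded into the heavy atom). Gasteiger charges use the
standard iterative partial-equalization scheme; the per-molecule charge sum
is validated against the total formal charge to 10⁻³.

The NNConv-style convolution passes edge attributes through an edge network
producing a per-edge weight matrix applied to the source embedding, with
mean aggregation; node updates are ReLU(root-transform + aggregate). The
equivariant variant uses messages φ_e(hᵢ, hⱼ, ‖xᵢ−xⱼ‖²) with internal
coordinate updates and an embedding-only readout, so class probabilities are
invariant to rigid motions by construction (verified to < 10⁻⁵, observed at
machine precision). Rotation augmentation emits, per graph, the original plus
one copy rotated about each of the x, y and z axes by an independent uniform
angle — read as one single-axis rotation per copy, not composed rotations.

Training: Adam (lr 10⁻³ default), softmax cross-entropy, global-norm
gradient clipping at 1.0, batch size 16 (64 after augmentation), per-graph
feature normalization with learnable affine applied *between* message layers
(normalizing after the last layer would zero the per-graph mean and collapse
the mean-pool readout — discovered the hard way), and retention of the
best-validation-loss checkpoint. Hidden width defaults to 64; tests use
8–32. Layer counts per variant: 3 MP (1 edge layer)/2 dense for the plain
variants, 4 MP (2 EL)/3 dense for the augmented variant, 3 MP/2 dense for
the equivariant one. The networks run on a purpose-built NumPy reverse-mode
autodiff engine (`models/_autodiff.py`) sized to exactly these layers.

## Forest track and evaluation

The forest exposes per-class probabilities as tree-vote shares (fraction of
trees predicting each class), matching the "most commonly predicted by the
trees" reading of top-N ranking. Defaults: 500 trees, unlimited depth; a
seeded random-search tuning hook accepts a space and a trial budget.
Top-N ties are broken by higher training frequency, then lower space-group
number.

The 1/N-scaled precision/recall tally: a listed true class contributes
tp = 1, an unlisted one fn = 1, and *every* incorrectly listed class
collects fp = 1/N — including the co-listed classes of a correct prediction
(the literal reading of "every space group assigned incorrectly"; the
alternative of waiving fp on correct predictions would raise precision).
Never-predicted classes have undefined precision and are reported as
missing, not zero, so macro averages are not silently deflated. The
frequency reference uses the training-split frequency order as a stand-in
for database-wide order (an explicit order can be supplied), evaluated as
the proportion of the *test* set covered.

## Synthetic generator

The generator defines the study conditions; real structure databases are
license-restricted, so every distribution here is an artifact choice, marked
as such:

* **Chemistry.** ~20 scaffold templates (aromatic and aliphatic rings,
  chains) × ~30 substituents covering the 18 counted functional groups,
  assembled as SMILES and embedded with seeded ETKDG. One conformer is
  cached per unique molecule and reused across records (polymorph families
  share a conformer by construction), which keeps the n = 5000 acceptance
  runs at desk scale; descriptor rows are cached per (molecule, conformer).
* **Labels.** p(c|mol) = softmax(log π_c + (Σ_f w_f s_{f,c} z_f)/T): π is
  the configured marginal (default: a synthetic uneven distribution over the
  25 / 10 most common organic space groups, dominated by P2₁/c and P‑1 —
  *not* measured frequencies), z are standardized true descriptor values,
  w the planted weights, s a fixed seeded ±1 pattern per (feature, class) —
  a shared scalar weight alone cannot discriminate classes under softmax —
  and T the noise temperature scaling only the planted score, so zero
  weights recover π exactly. Default planted features: planarity, symmetry
  operation count, alcohol/amide/acid counts, TPSA, NPR1; T = 0.35.
* **Constraints.** Chiral records (default fraction 0.1) are restricted to
  Sohncke labels by renormalizing the softmax over the Sohncke support;
  polymorph records (default rate 0.02) redraw from the softmax with the
  first label excluded.

What passing tests show: the pipeline recovers a planted, descriptor-mediated
label dependence far above the frequency baseline, and all bookkeeping
(balancing, splits, metrics, constraints) is correct. What they do not show:
that real molecules carry comparable signal — real space-group preferences
are weaker, and absolute accuracies here say nothing about accuracies
attainable on experimental data.

## Problem sizes used in the acceptance suite

Learnability uses n = 5000 records, 10 classes, 300 trees, one fixed seed;
the null controls use 5 seeds × 1000 records for the forest and 5 × 300
graphs (5 epochs) for the graph network; the symmetry oracle check covers
all fixtures plus 50 random ≤ 10-atom clusters; descriptor invariance covers
100 molecules × 100 rigid motions; the metric oracle 1000 random prediction
sets. These sizes are the package's documented defaults for its own
verification.

## Known limitations

* Point-group detection can miss axes that pass through neither an atom, a
  pair bisector, nor a principal axis (irrelevant for typical organics).
* The SMARTS set is a curated interpretation of the 18 named groups; edge
  cases (vinylogous esters, imides) follow the disambiguation rules above
  rather than any authoritative list.
* The GNN engine is CPU/NumPy and sized for desk-scale experiments, not for
  hundreds of thousands of molecules.
* Generator chemistry does not emulate real structure-database composition
  quantitatively, and conformers are force-field-free ETKDG geometries, not
  DFT-quality.
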