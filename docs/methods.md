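# Methods

## Scope and design

`pcmlab` is a proteochemometric (PCM) regression pipeline: one model maps a
concatenated ligand + protein descriptor vector to a scaled pIC50, so a
single regressor spans many protein targets and can, in principle, borrow
strength across related proteins. The package is organized as the pipeline
reads: `synthetic` (data with ground truth) → `curation` → `featurization`
→ `splits` → `models` → `conformal` → `evaluation`, with `workflows` wiring
full protocols and a thin `cli` on top. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; repeated runs are
bit-identical.

## Curation

Records are ChEMBL-style IC50 rows. A record is retained iff it parses,
has units `nM`, is not flagged a potential duplicate, has confidence score
≥ 9, its comment is not "inconclusive", its value is positive, its
charge-parent-standardized structure has molecular weight in [75, 800] Da,
and it matches no PAINS pattern (RDKit's built-in catalog, families A+B+C,
480 entries). Structures are standardized with RDKit's charge-parent
routine (largest organic fragment, then neutralization); the operation is
idempotent, and the retained set is independent of rule order because the
rules are conjunctive — the audit merely *attributes* each removal to the
first rule that fired, so input = output + Σ removals always holds.
Replicate measurements of a (standardized SMILES, protein) pair are
collapsed to the median IC50 (mean-of-middle-two for even counts), then
converted by pIC50 = 9 − log10(IC50/nM). Label scaling is a standard
scaler (population SD) fitted on training labels only.

## Featurization

* Ligands: 4096-bit ECFP6 (Morgan radius 3, folded, binary) plus 8
  physicochemical descriptors (MW, TPSA, HBD, HBA, logP, heavy atoms,
  rotatable bonds, ring count), all from RDKit.
* Proteins: 567 sequence descriptors — amino-acid composition (20),
  overlapping dipeptide composition (400, counts/(L−1)), and
  composition/transition/distribution (CTD) statistics (147) over the
  canonical seven physicochemical attributes with three residue groups each
  (hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility),
  shipped as a data file. For each attribute the 21 values are: 3 group
  fractions; 3 transition frequencies T(i,j) = (N_ij + N_ji)/(L−1) for the
  pairs (1,2), (1,3), (2,3); and per group the sequence-position
  percentiles (100·pos/L) of the first, 25%, 50%, 75% and 100% occurrence,
  where the k% occurrence is the ⌈k/100·n_g⌉-th occurrence of the group and
  an absent group contributes five zeros. Alphabet order is fixed
  (ACDEFGHIKLMNPQRSTVWY), dipeptides are row-major over it, and the CTD
  attribute order is the list above, so column identity is stable across
  runs.

The pair matrix is [fingerprint | physchem | protein] = 4671 columns.
Continuous columns (everything but the fingerprint) are standard-scaled
with mean/SD (population) fitted on the training rows and reused for
validation, calibration and test rows; zero-variance columns are centred
and left unscaled.

## Splits

Grouped splits (generic Bemis-Murcko scaffold; protein ID) shuffle the
group labels by seed and fill the training set greedily until the target
record fraction is reached, so no group spans training and validation and
the achieved fraction deviates from the target by at most the largest
group. The generic scaffold is the Murcko framework (ring systems +
linkers) with every atom mapped to carbon and every bond to single; all
acyclic molecules share one reserved empty-key group and therefore move
together. Fractions count records, not groups. The conformal calibration
split is a record-level random 80/20 split of the training set.

## Models

**Random forest.** scikit-learn `RandomForestRegressor`; defaults are the
selected configuration n_estimators=1000, max_features=sqrt,
min_samples_leaf=1, with the usual 3×4×5 grid ({100,500,1000} ×
{sqrt,log2,0.3,0.5} × {1,3,5,10,25}) available for exhaustive search scored
by validation MSE. Per-instance spread is the population SD of the
individual tree predictions.

**Feed-forward network.** Each fingerprint bit is a 2-category categorical
with its own learned embedding (2 dimensions per bit by default — a small
cardinality-based size for binary categories). Embeddings are concatenated
with the 575 scaled continuous features and passed through linear layers of
2000, 1000 and 500 units; each hidden linear output goes through ReLU, then
batch normalization, then dropout 0.25 (0.01 on the embedding outputs). The
final scalar passes a logistic squashing onto the training-label range
expanded by a factor 1.2 about its midpoint, which bounds extrapolation.
Optimization is Adam with decoupled weight decay 0.01 (applied to weights
and embeddings, not biases or batch-norm parameters) under a one-cycle
learning-rate schedule (cosine warmup from max_lr/25 over the first 25% of
steps to max_lr = 1e−2, cosine anneal to max_lr/1e4; defaults 20 epochs,
batch 256). The network is implemented directly on NumPy — forward and
backward passes are hand-written dense linear algebra running on BLAS —
which keeps the package dependency-light and the arithmetic fully
inspectable. Predictive spread is MC-dropout: the population SD over
repeated stochastic forward passes (default 100) with dropout masks active
and batch norm in inference mode; when both dropout rates are zero the
passes are identical by construction and the spread is returned as exactly
zero rather than accumulating BLAS round-off.

## Conformal prediction

Split (inductive) conformal regression with spread-normalized
nonconformity α = |y − ŷ|/λ, λ = spread + β (β = 0.01 by default, guarding
degenerate zero spreads; λ = exp(spread) is available as an alternative
scaler). For confidence 1−ε the half-width multiplier α* is the k-th
smallest calibration score with the finite-sample rule k = ⌈(1−ε)(n+1)⌉;
k > n yields an unbounded interval, which is reported, never clipped, and
excluded (with a count) from width summaries. The ceiling is evaluated
with a 1e−9 slack so that exact rank boundaries (e.g. 0.95·20 = 19) are
not pushed up a rank by floating-point round-up. Intervals are symmetric;
calibration pools all proteins. Expected coverage on exchangeable data is
k/(n+1) ≥ 1−ε — with n = 90 and ε = 0.05, k = 87 and expected coverage
87/91 ≈ 95.6%.

## Evaluation

MSE, Pearson r, and Kendall τ-b (tie-corrected; pIC50 ties occur). Pearson
and τ are reported as NaN for zero-variance inputs; MSE is always
computed. Per-protein tables include groups with more than `min_n`
(default 100) instances and are summarized by the unweighted mean ±
sample SD across groups. Residual correlation between two models is the
squared Pearson correlation of their residual vectors. RF feature
importance is the impurity importance; a model-agnostic permutation
importance (mean MSE increase under seeded within-column permutation) is
provided for the FFN, since no canonical importance exists for it.

## The synthetic-data generator

The generator defines the study conditions for all tests:

* **Proteins** — `n_families` = 6 families × 4 members; the first member
  is a random root sequence (length uniform in 150–250) and the others
  substitute each residue to a different residue with probability 0.05,
  giving within-family identity ≈ 95%.
* **Ligands** — a shipped template grammar: 14 ring-scaffold templates
  (each a distinct generic Bemis-Murcko framework) × 24 acyclic
  substituents; defaults use 12 scaffolds × 14 substituents = 168
  molecules, canonicalized and deduplicated. All grammar products are
  PAINS-free and inside the 75–800 Da window.
* **Labels** — half of the protein×ligand cross product is sampled
  (default ~2016 pairs). The latent function is sparse-linear over the
  *real* 4671 computed descriptors (z-scored per column over the generated
  entities; sparsity 0.02 → ~93 weighted features) plus ~9
  protein-feature × ligand-feature interaction products, affinely rescaled
  to mean 6.5 / SD 1.3 pIC50 — the publication-biased distribution shape of
  public IC50 corpora — and observed with Gaussian noise of SD 0.5 log
  units, the typical inter-assay heterogeneity of public IC50 data.
  Because the latent function lives on the same descriptors the models
  see, recovery tests are meaningful: an RF reaches validation Pearson
  r ≈ 0.8 on a random split at ~5000 pairs against a noise ceiling of
  ≈ 0.93.
* **Contaminants** — per-record (wrong units, confidence < 9,
  "inconclusive", duplicate flag, i.i.d. replicates) and per-molecule
  (an appended ene-rhodanine core guaranteeing a PAINS hit; an appended
  C55 chain pushing MW above 800 Da), each at a configurable rate. The
  manifest records exactly which (molecule, protein) pairs a correct
  curation retains, giving an exact oracle for the curation module.

Problem sizes throughout the test suite and protocols (~2000-pair default
datasets, ~5000-pair recovery runs, 20-repetition coverage protocols) were
chosen as the smallest sizes at which the statistical claims have adequate
power on a single CPU.

## What the generator does not emulate

Real medicinal chemistry (synthesizability, assay ontologies, activity
cliffs), structured noise (per-lab systematic shifts), and — importantly —
realistic scaffold novelty. The grammar shares all substituents across
scaffolds and the latent function is linear in ligand descriptors, so a
held-out scaffold's molecules remain partly predictable from substituent
features learned on other scaffolds, and only scaffolds whose
ring-system/junction fingerprint bits happen to carry latent weight are
genuinely hard. Consequently the held-out-scaffold split is harder than a
random split *in expectation* (mean validation MSE ≈ 0.43 vs ≈ 0.35 across
seeds, with individual held-out scaffolds reaching MSE > 1.7), but the
ordering is not guaranteed in every individual seed: with only ~12 scaffold
groups, which 2–3 groups land in validation dominates the per-seed outcome.
Passing tests therefore demonstrate correct mechanics and the expected
aggregate direction, not the (much larger) scaffold-split penalty seen on
real corpora with thousands of scaffolds.

## Numerical choices

Population (not sample) SD consistently for spreads, scalers and batch
statistics; even-count medians are the mean of the two middle values;
greedy grouped splits rather than bin-packing (seed-reproducible, error
bounded by the largest group); β = 0.01 additive spread smoothing;
unparseable SMILES are audited removals, not fatal errors; zero-variance
scaler columns default to scale 1; the FFN trains in float32, skips
terminal batches of size 1 (batch statistics need ≥ 2 rows), and seeds
bootstrap, initialization and dropout masks independently of data order.

## Known limitations

No Mondrian (per-group) conformal variants, no cross-conformal/jackknife+;
no tautomer or stereochemistry handling in curation; no count-based or 3D
descriptors; the FFN exposes epochs/batch/learning-rate as configuration
rather than searching them; CDDD-style learned molecular descriptors are
out of scope (they require an externally trained autoencoder).
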