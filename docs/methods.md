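# Methods

## Model and assumptions

`midfuse` implements a two-layer, mid-level fusion of multi-platform omics
feature tables. The statistical assumptions are those of linear discriminant
modelling: class information is carried by linear combinations of variables;
within-class variation is comparable across classes (a pooled within-class
covariance is meaningful); and the platforms measure the same underlying
samples, identified by exact, case-sensitive string ids. Nonlinear class
structure is out of model — it would be compressed away by both layers.

### Layer 1 — extended canonical variates per block

For a block X (n × p) with g groups, pooled within-group covariance

    S_w = Σ_i Σ_j (x_ij − x̄_i)(x_ij − x̄_i)′ / (n − g)

and between-group covariance

    S_b = Σ_i n_i (x̄_i − x̄)(x̄_i − x̄)′ / (g − 1),

the canonical directions maximize w′S_b w / w′S_w w. At p ≫ n the direct
eigenproblem S_w⁻¹S_b w = λw is unavailable, so the problem is rewritten as
the regression S_w B ≈ Y with Y's columns the g(g−1)/2 pairwise group-mean
differences, solved by PLS2 with a configurable number of latent variables.
W is the set of leading g−1 left singular vectors of B, unit-norm, each
column sign-fixed so its largest-magnitude entry is positive (reproducible
across linear-algebra backends). Scores are T = (X − x̄)W. For g = 2 the
pairwise-difference Y reduces to the single canonical difference; with
well-conditioned S_w and a full complement of latent variables, B collapses
to S_w⁻¹Y and W spans the classical eigen-solution exactly (a test asserts
principal angles < 1e−6).

Two numerical choices matter here:

* **Uncentered PLS.** The rows of the predictor matrix S_w are variables,
  not samples; the column centering of ordinary regression PLS would change
  the eigenproblem being solved. The NIPALS PLS2 used here therefore applies
  no centering or scaling. (sklearn's `PLSRegression`, which always centers,
  is used in the test suite as an independent cross-check on pre-centered
  problems, where both must agree.)
* **Reduced-basis solve.** S_w = X_c′X_c/(n−g) has rank ≤ n−g, and every
  NIPALS weight vector lies in range(S_w), so for wide blocks the regression
  is solved in the within-scatter eigenbasis (an (n−g)-dimensional problem)
  and mapped back. This is a change of basis, not an approximation; it makes
  a 7000-variable fit cost the same as a 40-variable one.

The divisors (n−g) and (g−1) follow chemometrics convention; the canonical
directions are invariant to this choice, which a test asserts by refitting
the eigen-oracle under alternative normalizations.

The inner latent-variable count is selected by venetian-blinds
cross-validation (default 7 splits, stratified by class, deterministic in
the input order): each candidate is scored by nearest-centroid
misclassification of held-out samples in score space, ties going to the
smallest count. Fold counts shrink automatically (with a warning) when a
class is too small.

For very wide blocks an optional screen keeps the top-k variables ranked by
the Euclidean norm of their rows of W, then refits both the scaling and the
eCVA model on the reduced raw columns (default for the emulated design:
k = 153, matching the low-dimensional block).

### Preprocessing

Per block, optional integral normalization (each sample row rescaled to a
constant sum; default 100) removes dilution effects for NMR-like data, then
a column scaling is fit on training samples only: mean-centering,
autoscaling, Pareto or vast scaling ((x−μ)/σ · μ/σ). SDs use the unbiased
n−1 denominator; zero-variance columns are dropped with a warning. Vast
scaling — autoscaling weighted by the mean-to-SD stability ratio — is the
default, reflecting that discriminant biomolecules in real feature tables
tend to be the well-measured ones while much of the noise lives in unstable,
low-stability features. Held-out samples are always transformed with stored
training statistics.

### Layer 2 — missing-value PCA on concatenated scores

The per-block training scores are concatenated into an n × Σ_b(g−1) matrix
with missing cells exactly where a sample was not measured on a platform.
Before the PCA the score columns are standardized with training mean/SD
(config `score_scaling`, default on). This standardization is load-bearing,
not cosmetic: platform score scales are incommensurate, and with
block-contiguous missing patterns the unstandardized EM-type PCA has a
degenerate direction along which imputed cells grow without bound while the
observed-cell fit stays flat.

The missing-value PCA itself initializes missing cells at observed column
means and iterates {re-center on current column means; rank-r SVD; replace
missing cells with the reconstruction} until the Frobenius change of the
imputed cells, measured relative to the RMS of the observed cells, falls
below 1e−9 (default; max 1000 iterations at the module level, 20 000 inside
the fusion layer where the matrix is tiny). The centered-SVD step is the
exact minimizer of the mean-plus-rank-r objective, so the observed-cell
reconstruction error is provably non-increasing — a property test asserts
it. Observed cells are never modified. Measuring convergence against the
imputed cells' own norm (the obvious choice) fails when the true imputations
are near zero, as standardized score columns make routine.

`r_global` defaults to all Σ_b(g−1) score columns: the PCA is then a loss-free
change of basis for classification, while interpretation and score plots use
the leading g−1 PCs. (Retaining only g−1 PCs for classification discards the
weaker platform's complementary information whenever the platforms'
strengths differ — measurably so on the synthetic design below.)

New samples are scored by least squares on their observed score coordinates;
samples observed on fewer platforms than r coordinates require the
minimum-norm solution (unidentified score components sit at the training
mean). The library-level `project_pca` keeps the stricter ≥ r-observed
contract unless explicitly relaxed; the classifier relaxes it.

### Validation and classification

The test set (default 20 %) is chosen by the Kennard–Stone max–min
algorithm — seed with the two mutually farthest points, then repeatedly add
the point with the largest minimal distance to the selected set — run per
class (stratified) on the autoscaled concatenation of the samples present in
every block; samples missing from any block always train. KS picks the
most space-covering (hence hardest) samples as the test set, a deliberately
conservative estimate. Classification is nearest class centroid in retained
PC space under pooled within-class Mahalanobis distance (Euclidean mode
available); ties break to the lowest class index. After validation the model
is refit on all samples for interpretation.

No fitted statistic — scaling, canonical directions, loadings, centroids —
ever sees a test sample; a test asserts the fitted model is bit-identical
under arbitrary perturbation of test-sample values.

### Interpretation

Global weights of block b's variables are W_b · (P_b / s_b), the canonical
directions times that block's PCA-loading rows with the score
standardization folded in, so rows refer to raw canonical scores. A group's
importance per variable is the projection of its global-weight row on the
unit vector to the group's centroid in the leading g−1 PCs, jointly
normalized over all blocks so max |importance| = 1; the sign encodes up- or
down-regulation in the target group (a mean-shift column is emitted as a
consistency check). Peptides roll up to proteins when ≥ 3 mapped peptides
share the majority importance sign; the protein value is the mean over the
agreeing peptides, dissenters excluded; zero importances count as positive
and a sign tie goes to the side with larger total |importance|.

Correlation networks are per class: all pairwise Pearson r over the class's
samples present in every block a pair involves (complete-pair deletion —
the data give no basis for imputing cross-platform pairs). Constant-in-class
variables get r = 0 (flagged) rather than being dropped, keeping node sets
stable across classes; pairs with < 3 usable samples get no edge. Edges
require |r| > threshold strictly (0.8 default: a correlation of exactly 0.8
is not an edge). Subnetworks are breadth-first expansions around seed
variables (default 2 layers, adjacency counting edges of any class). DOT
export is lexicographically ordered, hence byte-deterministic; node shape
encodes model importance (box vs ellipse) and edge style encodes class
(solid for the reference class, dotted otherwise); colors are a rendering
option, not part of the contract.

## The synthetic-study generator

No public dataset accompanies the method, so `midfuse.synthetic` generates
studies with the structure the method assumes, with full ground truth. The
default design: g = 3 balanced groups of 15 samples (healthy control,
peripheral inflammation, disease onset); a 2000-variable "proteomics" block
with a two-batch mean offset on 10 % of variables and 3 samples missing; a
153-variable "metabolomics" block with 5 samples missing; 4 latent background
factors per block for multicollinearity.

Class structure enters through two study-level biological processes with
zero-sum contrasts — disease-specific (−0.5, −0.5, 1.0) and general
inflammation (−1.0, 0.5, 0.5) — each with a shared unit-variance
within-class score. Each block reads both processes with its own strength
(proteomics 2.0/1.0 effect-size SDs, metabolomics 1.0/2.0) through planted
variable modules (24+12 peptides as whole 4-peptide protein groups;
6+12 metabolite bins) with random signs and loadings ≈ 2.2. Intensities
follow a multiplicative model, baseline × (1 + cv·z) (lognormal variant
available), with planted variables well-measured (CV 0.10) and noise
features spanning CV 0.10–0.40.

Three structural choices are deliberate and matter for what the tests mean:

* **Module structure, not isolated shifts.** Planted variables move together
  through their process factor. Besides being how disease signatures behave,
  this is statistically essential at p ≫ n: isolated independent mean shifts
  live in the tail of the within-class covariance, where no low-rank PLS
  solution can reach them — a pipeline tested only on such data would look
  uniformly broken, and one tuned to find them would not transfer.
* **Complementary strengths, not disjoint information.** Each platform sees
  both processes, one strongly and one weakly, so each platform alone
  discriminates all groups imperfectly while fusion can combine the two
  strong readouts. Effect sizes were calibrated so the single-platform test
  accuracies land in the 60–80 % band the method is intended for; with these
  defaults the fused model scores ≈ 0.86 against ≈ 0.71 per platform and
  matches or beats the better platform in ≈ 90 % of seeded studies.
* **Stability-coupled noise.** The variable-CV model is what gives vast
  scaling its documented edge over plain autoscaling here; under a
  constant-CV model the two coincide.

What the generator does not emulate: peak-shape artifacts, retention-time or
chemical-shift misalignment, censored/missing individual cells within a
block, non-Gaussian heavy tails, class imbalance, and any nonlinear
class structure. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the assumed linear module structure —
not robustness to upstream preprocessing failures.

## Problem sizes and runtime choices

The acceptance script runs 12 seeded default-size studies (~2 s each); the
heavier pipeline-level tests use 25 seeds at full size and small-block
variants elsewhere. The reduced-basis eCVA solve keeps a 2000-variable fit
at ~10 ms, so all sizes are the method's intended ones rather than
miniatures, except where tests explicitly construct small cases for oracle
comparison.

## Known limitations

* Test scores of wide-block eCVA models shrink toward the origin relative to
  training scores (the usual p ≫ n discriminant optimism), which is why even
  generously separated studies are not automatically classified perfectly;
  the Kennard–Stone test set, being extreme by construction, amplifies this.
* The EM-type missing-value PCA converges slowly (thousands of iterations)
  when retained rank is close to the number of observed coordinates in
  incomplete rows; the fusion layer compensates with a larger iteration
  budget and score standardization, but `low_level_fusion` on raw
  concatenated blocks may legitimately stop unconverged with a warning.
* The outlier screen uses classical-PCA score/orthogonal distances
  (chi-square and Wilson–Hilferty cutoffs); it is exploratory only, is not
  robust to clustered outliers, and is never applied automatically.
* Batch effects are represented but not corrected; the fusion is expected to
  tolerate, not remove, them.
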