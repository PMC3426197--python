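# Methods

## Model and procedure

All three criteria operate on a linear soft-margin SVM fitted to a
two-class expression matrix (samples × genes, labels ±1).  The decision
function is `sgn(w·x + b)` with `w = Σ_i α_i y_i x_i`; a sample with
`α_i > 0` is a support vector (SV).  The fit is delegated to libsvm
(scikit-learn's `SVC`, linear kernel) with a convergence tolerance of
1e−12, tight enough that symmetry properties the criteria rely on — label
negation flips `w` and `b` exactly, sample permutation leaves the fit
unchanged — hold to ~1e−12 on the weight vector at no measurable runtime
cost for these problem sizes.  A sample counts as an SV when its
multiplier exceeds `1e−8 · C`, a scale-free threshold matching common
solver epsilons.

Per-gene ranking criteria:

* **SVMRFE** — `w_j²`.
* **RSVM** — signed `w_j (m_j+ − m_j−)` with class means over *all*
  samples; ranking is by the signed value, exactly as the criterion is
  defined.
* **SVM-t** — the absolute Welch-form t-statistic of gene *j* computed
  over SV samples only.  With `n+ = n− = 1` it degenerates to
  `|u_j+ − u_j−|`; with a single SV on exactly one side, to the one-sample
  form using the multi-SV class's variance; otherwise the full Welch
  denominator `sqrt(s+²/n+ + s−²/n−)` is used.  Standard deviations use
  the n−1 convention, standard t-statistic practice.  When every sample is
  an SV the criterion coincides with the classical two-sample Welch |t|
  (asserted in the tests to 1e−10).

Backward elimination walks a strictly decreasing ladder of gene counts,
refitting and re-scoring at each level and keeping the top of the ranking
(ties broken by ascending original gene index, so runs are bit-for-bit
reproducible).  Ladders are built geometrically: `d_{i+1} =
round_half_even(ratio · d_i)`, decremented by one if rounding stalls and
clamped at the minimum.  Half-to-even is the rounding that reproduces the
reference 45-level sequence from 7129 at ratio 0.85 including its two
half-way cases (10→8, 450→382); plain nearest rounding agrees on all other
levels.

Cross-validated evaluation ("CV2") reruns the *entire* elimination inside
each training fold and predicts the held-out samples at every level with
that fold's level model; pooled misclassifications give the per-level
error.  Selection-on-all-data CV is available behind
`selection_in_folds=False` for comparison but is optimistically biased and
never the default.  Leave-one-out is the default scheme; stratified k-fold
is available for speed.  The final level is the CV-error minimiser, ties
resolved toward fewer genes.  A fold whose elimination fails is aborted,
logged and excluded from pooling, never silently skipped; a fold with a
single-class training part raises an error naming the fold.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `cost` (C) | 1.0 | soft-margin penalty bounding the dual multipliers; unitless. The SV counts, and hence SVM-t's trimming behaviour, depend on it, so it is exposed on every entry point and logged on every run. |
| SV tolerance | 1e−8 · C | multiplier threshold for SV membership |
| `ratio` | 0.85 | geometric ladder decay for real-data ladders |
| `d_min` | 5 | smallest ladder level |
| CV scheme | leave-one-out | `kfold` with seedable stratified folds as the faster alternative |
| standardisation | off | optional per-gene z-scoring for real data; simulated data are generated on a common scale |

## The synthetic-data generator

The generator emulates a fully specified Gaussian benchmark: balanced
two-class samples over 1000 genes; 150 genes at mean +μ in class +1 and −μ
in class −1, 150 genes with the signs reversed, 700 noise genes at mean 0
in both classes.  `N(a, b)` is read as mean `a`, standard deviation `b`.
Six scenarios cross μ ∈ {0.15, 0.25} with (informative sd, noise sd) ∈
{(0.5, 1), (1, 1), (1, 2)}.  Training sets have 50 samples per class,
evaluation sets 500 per class, and the study ladder is fixed to
{1000, 800, 600, 500, 400, 300, 200, 150, 100, 90, 80, 70, 60, 50}.
Per-run seeds are `base_seed + run`; all methods in a run share one
dataset (common random numbers, which only reduces between-method variance
of the comparisons), and both label orientations of a stability run share
one dataset seed.

What the generator does *not* emulate about real expression data:
gene–gene correlation, heavy tails and outliers, batch effects, and
intensity-dependent variance.  Passing the simulation checks therefore
shows that the criteria and the elimination machinery behave as designed
under independent Gaussian signal/noise — not that SVM-t will dominate on
any particular real dataset.

Reported metrics per (method, level): hold-out test error of the model
refit on the full training set at that level (the evaluation set is never
touched during selection); informative-gene recovery with denominator
`min(level, 300)` — above 300 retained genes the ceiling is the
informative count, below it the level size, so a perfect selection always
scores 1; and the SV count of the full-training refit (not a CV-fold
average).  Aggregates are means ± n−1 standard deviations over replicates;
a single-replicate aggregation reports sd 0 and is flagged degenerate.

## Numerical choices and degenerate inputs

* Zero within-SV variance in the SVM-t denominator: if the SV means still
  differ the gene scores +∞ (a perfectly separated constant gene is
  maximally informative among the SVs) and ranks first, ties broken by
  index; if means and variances are both degenerate the score is 0.
* A class whose SV set is emptied by the tolerance raises a labelled
  error — the criterion is undefined, and during elimination the error
  carries the ladder level.
* When every support vector sits at the box bound `α = C`, the intercept
  is only determined up to a KKT interval; the tests compare it by
  interval membership rather than point equality.
* Gene reports use the full-sample Welch test with Welch–Satterthwaite
  degrees of freedom (scipy); the rank of a gene is its position in the
  p-value ordering of *all* genes, reported for whatever subset was
  selected, so subset reports may skip rank integers.  P-values are
  reported raw; a Benjamini–Hochberg column is optional.
* Label mapping for real data: the user may name the positive class;
  otherwise the lexicographically first label maps to +1.  The mapping is
  always logged because the RSVM criterion is sign-sensitive in
  implementations whose solvers are not exactly symmetric.

## Design choices where the design was open

* **Solver and cost.**  The reference implementations' solver and cost
  settings are unreported; C = 1 is the package default and every
  SV-count-dependent result is documented as conditional on it.
* **RSVM label-switch behaviour.**  `w_j (m_j+ − m_j−)` is algebraically
  invariant under label negation (both factors flip sign).  With this
  package's deterministic, tightly converged solver the invariance holds
  in practice too, so the stability experiment reports Jaccard ≈ 1 for
  RSVM as well as SVM-t; reports of label-dependent RSVM selections can
  arise from solver or implementation asymmetries that this package
  deliberately avoids.  The experiment machinery (shared dataset per run,
  frequency tables, per-run Jaccard) is provided regardless.
* **Recovery denominator.**  `min(level, 300)` rather than a fixed 300:
  with a fixed denominator, recovery above 66.7% would be impossible at
  level 200, contradicting the benchmark's own reported values; the `min`
  reading also reproduces the characteristic non-monotone jump between
  levels 300 and 200.
* **Hold-out evaluation path.**  Test error at a level is that of the
  model refit on all training samples at that level (the evaluation set
  is an independent draw), not an average over CV folds.
* **Stability level.**  The ladder level at which switched-label
  selections are compared is a required parameter (default 50 in the CLI)
  rather than hard-coded.

## Problem sizes

The test suite runs the full pipeline at toy sizes plus two 30-replicate
benchmark scenarios (~15 s); `scripts/acceptance.py` uses 100 replicates
per scenario (~1 minute for five scenarios on one CPU), the benchmark's
own replication count.

## Known limitations

Linear kernel only — the correspondence between support vectors and
feature dimensions that motivates SVM-t is not available for nonlinear
kernels.  Two classes only.  No consensus/frequency-based selection across
CV folds (per-fold selections are recorded but the final set comes from
the full-data elimination).  Upstream microarray preprocessing
(normalisation, probe summarisation) is out of scope: the reader expects a
ready expression matrix.
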