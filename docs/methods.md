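# Methods

`connstab` implements a discriminative-edge discovery pipeline for
two-group resting-state functional-connectivity studies, together with a
synthetic-data generator that provides ground truth for every stage.

## The pipeline

**Temporal cleaning.** Each ROI time series is (1) linearly detrended,
(2) residualized by ordinary least squares against all confound columns
(motion parameters, their first differences, CSF/WM averages, spike
indicators) plus an intercept, and (3) band-pass filtered to 0.01–0.1 Hz.
The order is fixed. The filter is a second-order Butterworth applied
forward–backward (zero phase); only the band is part of the method
definition, the filter family is an implementation choice recorded here.
The regression design also carries the linear trend term so that the
projection is exact for confounds that were not themselves detrended (a
confound equal to a raw ROI column zeroes that ROI exactly). A
rank-deficient confound matrix is handled by minimum-norm least squares
with a logged warning — collinear columns change nothing.

Note on idempotence: re-cleaning cleaned data is *approximately* neutral.
Confound regression and detrending are projections (exactly idempotent),
but no IIR band-pass leaves its own output bit-unchanged — the squared
Butterworth magnitude response is below one everywhere except the band
centre, so a second pass attenuates band-edge content by up to ~50%. The
test suite therefore checks idempotence on band-centred content (where a
second pass changes the signal by well under 5%) rather than asserting an
unattainable exact fixed point.

**Connectivity.** Pearson correlation between every ROI pair; the strict
upper triangle in row-major order is the canonical edge vector (k runs
over i = 0..n−2, j = i+1..n−1), giving 4005 edges for 90 ROIs. Raw r is
the default feature; Fisher z is available but off, following the
pipeline's literal definition. Edge indices are 0-based internally,
1-based (`edge_0001`) in files and reports.

**Stage-1 screen.** Two-sided pooled-variance (Student) two-sample t-test
per edge on training subjects only; edges with p < P₀ survive. Zero
pooled variance yields p = 1 with a warning rather than NaN.

**Stage-2 CV-LASSO.** Training subjects are split into `k_inner` = 10
groups. Leaving out each group in turn, a LASSO is fit on the rest with
squared-error loss on the 0/1 labels (a linear-probability fit — the MSE
objective makes the regression-on-labels formulation the natural one).
The penalty is chosen per fit from a descending grid of 100 log-spaced
values from λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻³λ_max, by an *internal*
k-fold CV-MSE curve (default 5-fold) and the one-standard-error rule:
the largest λ whose CV-MSE is within one SE of the minimum, ties at the
minimum resolving to the largest penalty. This internal third nesting
level is a design choice this package makes explicit and configurable —
the procedure needs *some* curve to apply the 1SE rule to, and a
train-internal CV is the only leak-free option. Features are standardized
(mean 0, SD 1) on the fitting subjects inside every fit; held-out data
are transformed with the training parameters. The ten nonzero supports
are combined by an occurrence threshold: edges appearing in ≥ N of the 10
sets become the fold's LASSO features.

**Classifier.** Linear soft-margin SVM (hinge loss, penalty c) on the
selected edges, standardized on the training fold; patients (label 1) are
the positive class. No class weighting is applied despite the 39/30
imbalance — the protocol does not weight. Sensitivity = recall =
TP/(TP+FN); precision is emitted alongside. AUC is the Mann–Whitney
statistic with ties counted ½, identical to trapezoidal integration of
the emitted ROC curve.

**Outer evaluation.** A stratified k_outer = 10-fold split, repeated 100
times with fresh randomization; all selection and fitting happen strictly
inside each training fold. Metrics aggregate as mean ± SD (n−1) across
the 1000 test folds; decision scores pool into one ROC. Folds whose
selection comes back empty are recorded as failed and excluded from
aggregates, with the count reported. A master seed deterministically
spawns per-repeat, per-fold and per-permutation child seeds
(`numpy.random.SeedSequence`), so a fixed seed reproduces every number
bit for bit.

**Grid search.** (P₀, N, c) is searched over 11 × 10 × 20 = 2200 triples
(P₀ ∈ {0.001, 0.005, 0.01, 0.025, …, 0.2}, N ∈ 1..10, c ∈ 0.1..2 step
0.1) on one shared 10-fold split, choosing the triple with maximal mean
*test-fold* accuracy. This literal protocol is optimistically biased —
the test folds inform the hyper-parameters — and the docstring says so;
wrapping the search in an outer CV gives the honest estimate. Screening
p-values and CV-LASSO occurrence counts are computed once per
(fold, P₀) and shared across N and c, which makes the 2200-triple search
tractable. Ties resolve to larger N, then smaller c, then smaller P₀
(parsimony first), making the search deterministic.

**Permutation test.** B group-label permutations re-run the full pipeline
with the chosen triple (no per-permutation re-search; re-searching is
possible but costly and the protocol does not call for it);
p = (1 + #{null ≥ observed})/(B + 1) for mean accuracy and pooled AUC.
A permutation run in which every fold fails scores the chance rate
(majority-class accuracy, AUC ½) rather than being dropped, which keeps
the null honest. Reduced outer repeats per permutation are supported and
logged; the observed statistic is then computed under the same reduced
setting so observed and null stay exchangeable.

**Stability report.** Outer occurrence counts how many of the 1000
training folds selected each edge; edges strictly above the threshold
(default: half the folds, i.e. >500/1000) are the stable features. These
are then tested for a group difference with pooled t-tests on the *full*
sample under Bonferroni correction across the stable edges (Holm
available). The report prints the circularity caveat: these tests reuse
the sample the selection saw and are descriptive, not confirmatory. The
per-edge "weight" is the mean |standardized SVM weight| over the folds
where the edge entered the model — a definition this package fixes
explicitly, since importance summaries of this kind are otherwise
underdetermined; edges never entering a model are reported absent, not
zero.

## The synthetic generator

Defaults mirror the cohort scale the pipeline's defaults assume: 39
patients vs 30 controls, 90 ROIs (4005 edges), 205 timepoints at TR = 2 s,
and 5 signal edges.

*Time-series route.* A shared background correlation matrix comes from a
rank-3 Gaussian factor model plus a diagonal (giving mostly modest
off-diagonal correlations), normalized to unit diagonal. Signal edges are
pushed apart symmetrically by ±delta/2 (default delta = 0.3, group1 −
group0); positive definiteness is restored by clipping eigenvalues at
10⁻⁶ and re-normalizing, which moves planted differences by at most 0.02
(construction fails loudly otherwise, as it does when |r ± delta/2|
would leave (−1, 1)). Subject series are zero-mean Gaussians with that
correlation.

*Direct edge-table route.* Edge values are Gaussians on the Fisher-z
scale: per-edge baseline means ~ N(0.2, 0.1) shared by the groups,
between-subject SD 0.2, and signal edges separated by `effect_size_d`
SDs (default d = 1.5) with alternating sign across signal edges so both
group directions occur. This route is the fast fixture for statistical
tests: effects are exact and edges independent.

What the generator does *not* emulate: hemodynamics, physiological noise,
spatial autocorrelation between edges sharing an ROI (direct route),
non-Gaussian FC distributions, site/motion artefacts correlated with
group. Passing tests therefore demonstrate the *procedure's* correctness
and calibration, not performance claims about real patient data.

## Test and verification sizes

The verification suite checks, among others: exact structural counts
(4005 edges from 90 ROIs; 10 inner feature sets; 1000 fold evaluations
from 100×10 CV); numerical-core equivalence against independent oracles
(coordinate-descent LASSO vs a proximal-gradient minimizer, |Δβ| < 10⁻⁴;
libsvm's solution vs an SLSQP quadratic program on the primal hinge
objective, |Δobjective| < 10⁻⁶; trapezoidal vs rank-based AUC, < 10⁻¹⁰);
null calibration (20 no-signal 39v30 cohorts at full 4005-edge width,
plus 200 reduced-scale null simulations whose permutation p-values pass
a KS test against their discrete uniform at α = 0.01); signal recovery (50 cohorts at d = 1.5,
all 5 planted edges in the occurrence top-10 in ≥90%; mean accuracy
> 0.80 at d = 2); and an exact no-leakage guarantee (replacing any test
fold's features with noise leaves that fold's selected set unchanged).

Monte-Carlo checks use reduced problem sizes chosen to keep the suite
quick while leaving the tested property intact: reduced outer repeats
(1–2 instead of 100), a 30-value penalty grid with 3-fold internal CV in
simulation-heavy tests, and small cohorts for the permutation-uniformity
study (24 subjects, 28 edges, 19 permutations per simulation — the KS
reference distribution is the corresponding discrete uniform on
{1/20, …, 1}). The AUC-based permutation p-value is used for the
uniformity check because pooled decision scores are continuous; the
accuracy statistic is heavily tied, which makes its add-one p-value
conservative (super-uniform) by construction, not uniform.

A note on the null accuracy level: on no-signal data the pipeline's mean
CV accuracy centers at chance (≈0.50), *below* the majority-class rate
(39/69 ≈ 0.565). This is structural, not sampling noise: the screening
and CV-LASSO stages pick spuriously label-correlated edges, the training
folds become (near-)separable, and the unweighted SVM's held-out
predictions are then essentially label-independent fair coins — expected
accuracy q·p₁ + (1−q)·p₀ with q ≈ ½, i.e. 0.5. A pipeline would sit *at*
the majority rate only if its null classifier degenerated to majority
voting (q ≈ 1). The acceptance suite contains a calibration check
anchored at the majority rate that documents this discrepancy; the
operative guarantee is that null accuracy never exceeds chance-level
performance, i.e. there is no optimistic selection leakage.

## Known limitations

- The grid search follows the literal, optimistically biased protocol by
  default; honest nested evaluation must be requested explicitly.
- The LASSO-on-labels formulation is a linear-probability model; no
  logistic variant is provided.
- The stability threshold (>50% of folds) is a convention, not an
  inference; the FWE-corrected t-tests on stable edges are circular by
  design and flagged as such in every report.
- No volumetric image handling: inputs begin at ROI time series or edge
  tables.
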