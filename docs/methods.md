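# Methods

`mklfuse` implements a kernel-level fusion classifier for case/control
discrimination from tabulated, image-derived feature tables — the
setting in which structural MRI morphometry/intensity measures,
DTI diffusivity measures and resting-state functional-connectivity
z-scores are each summarized as a subjects × features table, acquired on
several scanners, with a sparse, modality-spanning disease signal.
This note records the model, the estimation choices, what the synthetic
generator does and does not emulate, and the numerical conventions.

## The classifier

Let subject *i* carry feature vectors *x_i^m* for modalities *m ∈ M*
and a label *y_i ∈ {+1, −1}* (+1 = case). Each modality gets its own
kernel *k_m(·,·)* (linear or Gaussian RBF on standardized, selected
features), and the fused kernel is the convex combination
*K = Σ_m w_m K_m* with *w_m ≥ 0, Σ w_m = 1*. The classifier is the
soft-margin SVM in its dual form,

    min_α  ½ Σ_i Σ_j α_i α_j y_i y_j Σ_m w_m k_m(x_i^m, x_j^m) − Σ_i α_i
    s.t.   Σ_i α_i y_i = 0,   0 ≤ α_i ≤ C,

with decision function

    f(x) = sign( Σ_i α*_i y_i Σ_m w*_m k_m(x_i^m, x^m) + b* ).

Because the weighted sum of PSD Gram matrices is PSD, any standard
kernel-SVM solver applies to the fused kernel; weights are not learned
by gradient methods but searched exhaustively on a simplex grid
(stride 0.1 by default: 66 candidate vectors for three modalities),
jointly with the penalty *C* (eight log-spaced values, 10⁻⁴…10³), by
mean validation AUC over an inner stratified 5-fold CV. Ties are broken
deterministically: fewer nonzero weights, then smaller *C*, then
lexicographic weight order. Setting *w_m = 0* drops a modality, which is
also how missing modalities and the bimodal baselines are expressed.

### Dual solver

SMO with maximal-violating-pair working-set selection on the
precomputed fused Gram. Each pairwise step solves its two-variable
subproblem exactly (curvature *K_ii + K_jj − 2K_ij*, clipped at 1e−12),
so the dual objective is non-increasing by construction. Stopping rule:
maximal KKT violation ≤ 1e−6 (configurable), cap 10⁵ pair updates.
The offset *b\** is averaged over all unbounded support vectors
(0 < α < C) rather than taken from a single one — same value in exact
arithmetic, better conditioned in floating point; if no unbounded
support vector exists, the midpoint of the feasible interval is used.
The pairwise-update loop is JIT-compiled (numba), which makes the
exhaustive weight × C search practical; during the search the solver
runs at a relaxed KKT tolerance (1e−4, since validation AUC only needs
a ranking) with warm starts across the ascending C grid, while final
fits use the full 1e−6. The solver is verified against a generic
constrained-QP oracle (SLSQP) on small random instances.

### Probabilities

Threshold metrics are defined at probability cutoff 0.5. Decision
scores are mapped to probabilities by Platt scaling
*P(y=1|s) = 1/(1+exp(As+B))*, fit by regularized maximum likelihood
(Newton with backtracking) on inner-CV validation scores — never on the
scores of the same model evaluated on its own training points, which
would be optimistically compressed. AUC is computed on raw scores
(rank-invariant, so calibration cannot change it).

### Kernels

Features are standardized per training fold (mean 0, SD 1; train
parameters applied to the test fold). The RBF bandwidth defaults to the
median heuristic γ = 1/(2·median²) of pairwise training distances,
recomputed per fold from training rows only; a fixed γ can be
configured. Default kernel assignment: RBF for the structural and
functional tables, linear for the diffusion table. No kernel centering
or trace normalization is applied: after standardization the convex
combination already keeps scales comparable, and adding it changes the
model class. Weight arithmetic runs on an exact integer grid (k/steps)
to avoid float drift.

## Feature selection

All-relevant selection with shadow features, per modality, on each
outer training fold only. One iteration: append an independently
row-permuted copy of every column (padded to at least five shadows so
the max-shadow reference never rests on too few decoys), score all
columns with a random-forest importance provider (mean Gini-impurity
decrease, 500 trees, √d features per split by default; the provider is
a plain callable contract, so any ensemble scorer can be substituted),
and count a hit for originals scoring strictly above the best shadow.
Cumulative hits are referred to Binomial(trials, ½): the confirm and
reject branches are each tested one-sided at α = 0.01 after Bonferroni
correction over all original features — the canonical reference
defaults. A shrinking correction denominator was deliberately rejected:
it loosens the threshold exactly when only a few spuriously persistent
features remain, which measurably inflates the false-confirmation rate
on pure noise. Features still tentative at the iteration cap (100) are
conservatively treated as not selected. Confirmed features stay in the
forest (they shape the shadows' competition); rejected ones leave.

Sequential caveat: the per-iteration binomial test involves optional
stopping, so a feature whose in-sample association is spurious but
stable can eventually cross any fixed threshold given enough
iterations. The α = 0.01 / cap = 100 combination keeps the expected
number of such false confirmations at or below about one per fifty
pure-noise datasets of the sizes tested.

### Selection stability

With R repeats of K-fold CV, each modality accumulates N = K selected
sets per experiment. Under the null that selection is random, a
feature's selection count over N runs is Binomial(N, p̂) with p̂ the mean
selected fraction of the modality's candidate pool. Upper-tail p-values
are Holm-adjusted across the modality's features; features significant
at 0.05 in *every* repeated experiment (intersection rule) form the
final reported set.

## Batch harmonization

Parametric empirical-Bayes location-scale harmonization. Per feature:
standardize by the pooled residual SD after an OLS fit of batch
indicators plus covariates (age, sex by default; the diagnosis label is
never accepted as a covariate); estimate per-(batch, feature) additive
γ and multiplicative δ² effects; shrink them toward batch-level priors
(normal for γ, inverse-gamma for δ², hyperparameters by method of
moments) via the conditional-posterior fixed point, iterated to
relative change < 1e−4 (cap 100); correct standardized residuals by
(·−γ*)/δ* and restore the grand mean and covariate effects. The
implementation reproduces Bioconductor `sva::ComBat` to ~1e−6
(differences bounded by the shared stopping rule), and that routine
serves as an independent oracle in the test suite. Exact idempotence is
*not* a property of the EB estimator — re-fitting shrinks residual
noise and moves values at the sub-percent level — so the test suite
checks second-pass changes < 0.02 pooled SD rather than machine zero.
A single-batch fit is made an exact no-op (γ* = 0, δ*² = 1): there is
no batch effect to remove, and dividing by a noise-level scale estimate
would only perturb the data.

Fit scope: by default the model is fitted on the outer training fold
and applied to both folds (no test-fold information enters the
estimates). A `whole_sample` switch fits on the whole dataset before CV,
reproducing the common whole-sample practice at the cost of a mild
leakage channel.

## Cross-validation protocol

Outer stratified 10-fold CV, repeated 10 times with fresh divisions;
all modalities and all compared models share the same division within a
fold, so model contrasts are paired at fold level. Within each outer
training fold: optional harmonization fit, per-modality selection,
standardization, kernels, inner 5-fold grid search over (w, C), retrain
at the winner on the full training fold, calibrate, evaluate once on
the held-out fold. Reported metrics (accuracy, sensitivity,
specificity, F1 at cutoff 0.5, and AUC) are means over all folds ×
repeats. Baselines: per-modality single-kernel SVMs (linear and RBF),
early fusion (concatenation of all selected features into one kernel),
every bimodal fusion, and the trimodal fusion. Paired model comparisons
over fold-level AUCs are available as paired t or Wilcoxon tests
(config-exposed; no default is privileged because the choice is
genuinely open).

If selection confirms nothing for a modality on some fold, the full
candidate pool is used for that modality-fold (flagged, and recorded as
an empty set in the stability accounting); zeroing the modality's
kernel would silently change the model class, and the weight search can
down-weight an uninformative modality on its own.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
at the scale of a matched case/control neurodevelopmental imaging
study: by default 116 cases and 116 controls (45 F / 71 M in each
group, race composition matched exactly), age ≈ 118.4/118.9 ± 7.7
months per group, three modalities with candidate pools of 1184 / 1182
/ 338 features, several scanner batches assigned independently of the
label, and a sparse informative set per modality (5 / 10 / 13 by
default, spread across correlation blocks rather than clustered).
Features are block-exchangeable Gaussians (block size 10, ρ = 0.3):
informative columns gain +δ (default 1.0 SD) in cases; each batch adds
a per-(batch, feature) shift (magnitude 0.3 × N(0,1) draws) and
multiplies noise by `batch_scale^U(−1,1)` (default 1.1); all features
drift mildly with age (0.1 SD per SD of age), giving the harmonizer a
real covariate to protect. A confounded mode correlating batch with
label exists but is off by default, since the emulated design matches
groups across scanners.

What the generator does *not* emulate — and hence what green tests do
not establish about real data: heavy-tailed and bounded marginals
(volumes, z-scores), heteroscedastic units across feature families,
long-range correlation structure beyond exchangeable blocks,
site-by-covariate interactions, missingness, and label noise in the
diagnosis itself. Effect sizes of real single-feature imaging markers
(typically δ ≪ 0.5) are far below the default planted δ = 1; the
default is chosen so that selection power, not raw signal strength, is
the property under test.

## Problem sizes used in the shipped checks

The repository's end-to-end checks run on scaled-down instances chosen
to exercise every stage at desk scale. The fusion-ordering and
leakage-null experiments use 80 subjects per group and 12 features per
modality with 4 informative each at δ = 0.5, the signal split
disjointly across modalities. This deliberately reproduces the
weak-signal regime the pipeline is designed for — single modalities in
the 0.6–0.7 AUC range, fused models near 0.7–0.75 — because fusion has
no headroom once a single modality saturates (with δ = 1 and five
markers a lone modality already exceeds AUC 0.9, and the ordering
between fused and unimodal models becomes a coin flip at the noise
level). The search uses weight stride 0.2, a three-point C grid
{10⁻³, 0.1, 10}, and a reduced selector forest (35 trees, 20-iteration
cap). The selection power check runs on the default cohort's
functional-connectivity-sized modality (338 candidates, 150 trees,
30-iteration cap); the noise-calibration check uses 50 datasets of
200 × 50 (100 trees, 40-iteration cap). These are the package's own
reference conditions and
are stated here so results are interpreted at the scale they were
computed.

## Known limitations

- The weight grid is exhaustive, so cost grows combinatorially with the
  number of modalities (C(10+M−1, M−1) solves per C value at stride
  0.1); beyond ~5 modalities a gradient-based MKL is the right tool.
- The selector inherits the optional-stopping caveat above; its
  confirmed sets should be read through the stability test, not as
  individual certainties.
- Platt calibration assumes a sigmoidal score-to-probability link;
  with tiny validation sets the map can be steep, making the 0.5-cutoff
  metrics noisier than AUC (which is unaffected).
- Harmonization assumes batch effects are location-scale per feature;
  site-by-biology interactions are outside the model.
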