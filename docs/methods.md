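# Methods

## The inference problem

Given k perturbation experiments over the same gene panel — each a
treatment time course `Xⁱ` (genes × Nⁱ time points) with a matched
replicated control `X^{c,i}` — the goal is a directed, signed network of
transcription-factor (TF) → target regulation supported by all k data sets
simultaneously. Three modelling assumptions drive the formulation:

1. **Sparsity** — each gene is regulated by a small number of TFs, so
   the per-response regression carries an L1 penalty.
2. **Cross-condition coherence** — the regulatory program is largely
   shared across conditions, so the k condition-specific coefficient
   blocks are tied by a fusion penalty on their consecutive differences.
3. **Differential-behavior similarity** — a TF that responds to a
   perturbation is a more plausible direct regulator of a gene that also
   responds (and vice versa for unaffected pairs), so each L1 term is
   weighted by the dissimilarity of the pair's differential-expression
   probability profiles.

Per response gene Y the fitted program is

    min_b ||Y - X b||² + λ₁ ||D₁ b||₁ + λ₂ ||D₂ b||₁

with X block-diagonal over conditions (rows = Σᵢ Nⁱ time points, columns
= k blocks of the P regressors), D₁ = diag(w¹, …, wᵏ), and D₂ the
(k−1)·P fusion rows (+1/−1, P columns apart). The order of the condition
blocks — hence which pairs the fusion chains — is arbitrary but fixed at
load time.

## Differential-expression probabilities

The weights require, per condition, a genes × time-points matrix of
probabilities of differential expression. These come from an
empirical-Bayes moderated-t hierarchy applied to each per-time-point
contrast (treatment value minus control-replicate mean, on the already
log-scaled input values):

* Gene-wise residual variances `s_g²` (control replicates, d = m−1 df)
  are shrunk toward a prior: the hyperparameters (d₀, s₀²) of a scaled
  inverse-chi-square prior are fitted by moments matching on `log s_g²`
  (mean and variance of `log s² − ψ(d/2) + log(d/2)` identify both; a
  non-positive excess variance yields d₀ = ∞, i.e. homogeneous variances,
  capped at 1e8 for numerics). Zero-variance genes are excluded from the
  fit and shrink fully to the prior.
* The moderated t is the contrast over `s̃_g √v` with
  `s̃_g² = (d₀s₀² + d s_g²)/(d₀+d)` and `v = 1 + 1/m` the unscaled
  contrast variance; it has d₀+d degrees of freedom.
* The B statistic is the log posterior odds of differential expression
  under a two-component model: with prior probability `prior_p` (default
  0.01) the contrast carries extra prior variance v₀, scaling the t by
  √r, r = (v+v₀)/v. Evaluated via `log1p` so it is overflow-safe and
  strictly increasing in |t| whenever r > 1. The probability is
  `expit(B)`.
* v₀ is not identifiable from any printed protocol, so it is estimated
  from the top `prior_p` fraction of |t| by method of moments
  (`r ≈ median(t²)/ (df/(df−2))`), falling back to v₀ = 4v when the tail
  shows no excess spread. Both the estimate and a fixed v₀ override are
  exposed. Because B is monotone in |t| at fixed hyperparameters, the
  downstream weights are insensitive to moderate mis-estimation of v₀.

Externally computed probability matrices (e.g. a limma workflow run
elsewhere) can be injected verbatim via `supply_probabilities`, which is
also the route for conditions with fewer than two control replicates.

## Penalty weights

`w^i_{Y,j} = (1/Nⁱ) Σ_t |pr_{Y,t} − pr_{j,t}|` — the mean absolute
difference of probability profiles. It is zero iff the profiles are
identical, bounded by [0, 1], symmetric with zero diagonal as an all-pairs
matrix, and a metric (triangle inequality holds), all of which are tested.
Averaging by 1/Nⁱ (rather than the raw sum) makes weights comparable
across conditions with different numbers of time points; when all Nⁱ are
equal the two conventions differ only by a rescaling of λ₁.

## Stacking and standardization

Within each condition block every regressor column is centered and scaled
to unit sample SD over that condition's time points, and the response is
centered per condition; no intercept is fitted. L1 penalties are
scale-sensitive and the input conditions may sit on different dynamic
ranges, so per-block standardization is the default (configurable,
`standardize = off`). Coefficients are reported on the standardized
scale; signs are unaffected. A constant (zero-variance) column is set to
zero rather than divided by zero. A gene never regresses on itself: when
the response is itself a TF its column is dropped from every block, giving
P−1 coefficients per block. Unequal Nⁱ are supported; the row count is
Σᵢ Nⁱ.

## Solver

**LQA (production path).** Each |u| in the penalty is majorized by the
quadratic `u²/(2√(u₀²+ε)) + const` around the previous iterate, so every
iteration solves

    (XᵀX + (λ₁/2) D₁ᵀA₁D₁ + (λ₂/2) D₂ᵀA₂D₂) b = XᵀY,   A = diag(1/√((Db₀)²+ε))

by Cholesky factorization. This is an MM scheme for the ε-smoothed
objective, so that objective is non-increasing across iterations — the
test suite asserts the whole path. Initialization is a deterministic
ridge solve (penalty `1e-3·tr(XᵀX)/p`). Defaults: ε = 1e-8, at most 500
iterations, convergence at max |Δb| < 1e-8. With these constants the LQA
objective agrees with an independent convex solution to within 1e-4
relative on random instances (tested over 50 draws).

A coefficient whose true minimizer is exactly zero is parked by the
smoothed iteration at magnitude ~√ε (up to a few times that near the
selection boundary); the reporting threshold (default 1e-3) converts
these to exact zeros. Standardized coefficients of real effects sit
orders of magnitude above it.

**ADMM (test oracle).** The same convex program is solved independently
by ADMM on the split z = Db with row-wise soft-thresholding and residual
balancing, guarded to small instances. It exists so that solver
correctness is a dual-route check, never a self-comparison.

**Cross-validation.** (λ₁, λ₂) are selected on the grids
{0.05, 0.1, 0.5, 1, 1.5} × {0.1, 0.5, 1, 1.5, 2} by k-fold CV (default 10
folds) minimizing mean held-out squared prediction error. Folds are
stratified by condition block — every fold, and therefore every training
split, samples every condition; if the smallest block has fewer rows than
folds the call fails with guidance to lower `cv_folds` rather than
silently orphaning a block. Fold assignment is seeded and round-robin
within each block. Exact score ties break toward the larger λ₁+λ₂ (then
larger λ₁), i.e. the sparser, more fused model. Fold fits relax the β
tolerance to 1e-6 (they only rank penalty pairs); the final refit on all
rows uses full precision. Standardization is computed once on the full
stacked design; CV subsets rows of that design.

## Network assembly

Each response is an independent regression, parallelized over workers
(joblib); every response draws its CV folds from its own seed stream
(derived from the study seed and the response's rank in the sorted
response list), so results are bit-identical for any worker count or
response order. Regulators with a non-zero coefficient in at least one
condition become edges. The consensus coefficient is either the
block value of largest magnitude (default, sign preserved from that
block) or the arithmetic mean of the blocks. Normalized weights divide
|consensus| by the largest |consensus|; edges are ranked by descending
weight with lexicographic (regulator, target) tie-break and the top-n
retained (default 100,000 — effectively "all" at desk scale). Signed
pre-normalization coefficients ride along: the regulatory-type call needs
them, and normalization never touches signs.

## Evaluation

The scoreable universe is every ordered (regulator, target) pair with
self-pairs excluded; pairs missing from the edge list score 0. ROC uses
the mid-rank tie convention, so AUROC equals the Mann-Whitney probability
that a random true edge outranks a random non-edge (asserted against a
brute-force enumeration on toy universes). AUPR uses step integration.
TPR at a target FPR (default 0.03) reads the step ROC curve at the
largest achieved FPR not exceeding the target — a documented convention,
since interpolation would report values never actually achieved. The
selector value is the normalized weight of the highest-ranked true
positive (0 with a warning if none is retained). The OverallScore of a
method across data sets is the average of the geometric means of its
AUROCs and of its AUPRs. Type fractions: of the gold activating
(repressing) edges, the fraction predicted with the correct sign; TP is
the fraction of gold edges predicted irrespective of sign; TN the
fraction of non-gold pairs not predicted. The TN denominator is taken
over the same ordered scoreable universe as the ROC analysis — the
benchmark convention leaves it undefined, so the internally consistent
choice is used and noted here.

## Synthetic studies

The generator emulates the *shape* of multi-condition perturbation
microarray studies on a log₂ scale: gene baselines ~N(8, 1); TF
treatment courses are moving-average-smoothed white noise (SD 0.6) —
smooth but full-rank, so the regression is identifiable — plus, for the
TFs perturbed in a condition (each TF with probability 0.5, at least
one), a saturating shift `±U(1.5, 2.5)·(1−e^{−t/2})`; target courses are
the planted linear combination of TF deviations plus N(0, noise_sd);
controls are baseline plus replicate noise. Defaults: 10 TFs, 30
targets, 2 regulators per target (|effect| ∈ [0.5, 2], signs equiprobable),
k = 3 conditions × 8 time points, 4 control replicates, noise SD 0.3.
A `saturation_scale` option passes target inputs through `s·tanh(x/s)`
for robustness checks under mild nonlinearity.

What the generator does **not** emulate: probe-level noise structure,
normalization artefacts, indirect/cascade regulation (targets regulating
targets), feedback loops, TF activity that is decoupled from TF mRNA, or
unequal time grids. Passing recovery tests therefore demonstrates
correctness of the machinery under the model's own assumptions, not
field performance on real microarray compendia.

On these defaults the full pipeline reaches AUROC ≳ 0.85 against the
planted truth with ≥ 98 % sign agreement on recovered true edges
(seeds 1–3; the test suite asserts AUROC ≥ 0.8 and ≥ 70 %). The
end-to-end runs use 5 CV folds: stratified CV requires folds ≤ min Nⁱ,
and with 8 time points per condition the protocol default of 10 folds is
infeasible; 5 halves the fit count relative to 8 while keeping ≥ 1 row
per condition per fold.

## Degenerate inputs and numerical conventions

* Loading rejects missing values, duplicate gene IDs, and non-numeric
  cells with distinct named errors; genes absent from some conditions are
  dropped with a warning (the stacked model needs every regressor in
  every block).
* Conflicting duplicate signs in a gold standard are an error; agreeing
  duplicates collapse with a logged warning.
* An all-zero network evaluates at AUROC 0.5 (all pairs tie at score 0)
  and selector value 0.
* Cholesky factorizations add a 1e-10-scaled jitter on failure (can occur
  at λ = 0 with collinear designs).
* All randomness (CV folds, simulation) flows from explicit seeds; two
  runs with the same config and inputs produce byte-identical output
  files, serial or parallel.

## Known limitations

* The fusion chain couples only consecutive condition pairs in load
  order; with k > 3 a different ordering changes the penalty (though not
  the k = 2 or λ₂ → ∞ limits).
* CV selects one (λ₁, λ₂) per response; no information is shared across
  responses.
* The B-statistic stage assumes a single two-group contrast per time
  point; multi-factor designs should compute probabilities externally and
  inject them.
* Coefficients are reported on the standardized scale; converting to the
  raw-expression scale requires dividing by the stored per-column scale
  factors (`StackedRegression.column_scale`).
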