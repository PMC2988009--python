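# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `polyrisk`, in the spirit of a
statistical package's methods appendix.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The problem and the modelling frame

Given case-level tabular data with a four-level outcome (benign, borderline,
primary invasive, metastatic invasive) the goal is a *polytomous* risk
model: for every case a probability for each event, nonnegative and summing
to one.  Two routes are implemented:

1. **All-at-once** models fit all events jointly: multinomial logistic
   regression (MLR) and its kernelized version (MKLR).
2. **Combinations of dichotomous models**: one classifier per pair of events
   (six for four events), each trained only on the cases of its two events
   and applied to every case, then recombined.

### Pairwise coupling

The six conditional estimates π̂_ij = P(event i | case, event ∈ {i,j}) are
coupled by solving

  π_i = Σ_{j≠i} π̂_ij (π_i + π_j)/(k−1) for all i,  with Σπ_i = 1, π_i ≥ 0.

Implementation: the k homogeneous equations are stacked with the
normalization row and solved by least squares.  If the unconstrained
solution leaves the simplex, the system is re-solved with the normalization
row weighted by 10⁶ under box constraints [0,1] (`scipy.optimize.lsq_linear`)
and the result renormalized; this always returns a simplex vector, and on
consistent inputs (π̂_ij = π_i/(π_i+π_j)) it reproduces π to ≤10⁻⁸ (tested
on 1000 random simplex draws).  The solver choice is ours; the defining
system and constraints are as printed above.

### Nested tree

The sequential alternative chains three dichotomies — benign|malignant,
borderline|invasive among malignant, primary|metastatic among invasive —
and multiplies the conditional probabilities, which sums to one by
construction.

## Classifiers

**Logistic / multinomial regression.**  Newton–Raphson maximum likelihood
with step-halving, no shrinkage or penalty (deliberately: the kernel models
carry the regularization story).  Convergence at max |score| < 10⁻⁸, cap
100 iterations.  Quasi-complete separation — a real possibility in
one-versus-one fits on the rare borderline (5 %) and metastatic (4 %)
classes — is flagged whenever any coefficient exceeds 15 in absolute value;
the capped fit is kept usable for ranking but `converged` is set false and a
near-singular Hessian is ridge-stabilized (10⁻⁸ × mean diagonal).  The
threshold is on raw coefficients, so predictors on extreme scales could
false-flag; the packaged profile's scales are nowhere near that regime.

**LS-SVM.**  One symmetric linear system per fit.  Internally the dual is
stored in the label-free parameterization f(x) = Σ α_i K(x_i,x) + b; the
KKT residual and Σα_i y_i = 0 are exposed and tested to ≤10⁻⁸.  A jitter of
10⁻¹⁰·tr(K)/n is added to kernel diagonals before solving.  Predictors are
standardized to training mean/SD inside every kernel model (Gaussian
kernels are scale-sensitive); the transformation is stored on the model.

*Probabilistic output.*  The full hierarchical Bayesian evidence framework
for LS-SVMs is **not** reproduced.  Instead the latent training outputs are
summarized per class by a Gaussian (mean, SD), and the posterior event
probability follows from Bayes' rule with the development data's outcome
prevalences as priors.  Hyperparameters (γ, σ) are tuned by stratified
5-fold CV on the c-index rather than by evidence maximization.  This
preserves the operative contract — dichotomous event probabilities from the
LS-SVM output with data-prevalence priors — in a fully testable form; it is
a documented approximation, not a reconstruction.  Degenerate latent spread
(SD ≤ 10⁻¹²) falls back to a hard 0/1 output with a warning.

*Fast leave-one-out.*  With M the (n+1)×(n+1) system matrix, the LOO
residual is α_i/[M⁻¹]_ii (the dual form of e_i/(1−h_ii)); tested to agree
with n explicit refits to ≤10⁻⁸.

**KLR / MKLR.**  Penalized (multinomial) negative log-likelihood over a
kernel expansion, penalty (λ/2)·α'Kα per class.  Each IRLS step solves a
weighted system with LS-SVM structure `[[0, 1'],[1, K + λW⁻¹]]·[b; α] =
[0; z]`; global step-halving makes the penalized objective monotonically
non-increasing.  Convergence at objective change < 10⁻⁸ (10⁻⁶ and 40
iterations inside CV tuning only, where only the c-index *ranking* of grid
points matters).  MKLR uses a reference-class softmax with diagonal working
weights per class, so its two-class special case is algebraically identical
to KLR (tested to 10⁻⁶).  Limits: λ→∞ gives the class prevalences; linear
kernel with λ→0 matches unpenalized logistic regression to 10⁻³.

**Hyperparameter grids.**  γ and λ default to 13 (7 in the method recipes)
log-spaced points in 10⁻³..10³; σ to 7 log-spaced points around the median
pairwise distance.  Ties in CV go to the most-regularized point (largest λ
or smallest γ, then largest σ).  The original study's exact grids and seeds
are unrecoverable; these defaults are conventional and overridable.  The
packaged kernel method recipes use the linear kernel by default — the fast
R1U selection that motivates them is linear-kernel-only — with the Gaussian
kernel available per spec.

## Variable selection

**LR track.**  Candidate sets from forward-stepwise (entry/removal p =
0.05, likelihood-ratio tests) and backward elimination; candidates are
scored by AIC = −2ℓ̂+2p and BIC = −2ℓ̂+p·ln n from the full-data fit plus the
mean per-event c-index from R runs of stratified F-fold CV out-of-fold
predictions (defaults R=20, F=5, seeds 1..R).  "Manual" selection is
supported as user-supplied sets; a human-in-the-loop step cannot be coded.

**R1U track.**  Forward selection for linear-kernel LS-SVMs.  Adding
variable v updates the kernel K ← K + x_v x_v′; the system inverse is
updated by Sherman–Morrison, LOO outputs read off the diagonal, and the LOO
c-index re-tuned over the γ grid at every step.  The procedure is exactly
equivalent to naive refit-everything forward selection (tested: identical
variable order, γ choices, and c-indexes to 10⁻⁸ across seeds).
Tie-breaking everywhere: higher c-index, then fewer variables / earlier
column order, then smaller γ.

**Budgeted coordination.**  The original study "intertwined" the six
pairwise selections while controlling the total variable count but did not
publish the recipe.  The package formalizes it as a greedy procedure:
repeatedly grant the single (pair, variable) addition with the largest
mean-CV c-index gain, subject to a global budget of distinct variables and
3–5 variables per pair.  This formalization is an invention of this
package, tagged as such.

## Evaluation

**Polytomous c-index.**  Over quadruples with one case per event, count the
events whose own predicted probability is strictly largest for the case of
that event, average, divide by 4.  The quadruple sum factorizes per event
into a product over the other events of the fraction of strictly-smaller
cases, giving an O(n log n) algorithm tested to equal brute-force
enumeration exactly.  *Ties earn no credit* — the defining phrase is
"largest", and for continuous model outputs ties have measure zero; the
consequence (an all-uniform classifier scores 0, not 0.25) is deliberate
and tested.  Chance level for label-independent continuous outputs is 0.25.

**Pairwise c-indexes.**  For one-versus-one ensembles the pair's own model
output is the score (default); for true polytomous models the renormalized
ratio π_i/(π_i+π_j), the coherent conditional probability, which reduces to
the pair model's output under consistency.  Both are exposed.

**Calibration.**  Loess (locally weighted linear regression, tricube
weights, default span 0.75, via statsmodels lowess) of the event indicator
on the predicted probability, evaluated on a 100-point grid and clipped to
[0,1]; one curve per event.

**Confidence intervals.**  The original report does not state its CI
method; the package substitutes a percentile bootstrap, resampling cases
stratified by event (B=1000 default, seeded), with paired resamples for
model differences.  Resamples losing an event class are redrawn (cap 10·B).

## Synthetic-data generator

Real cohorts are unavailable, so the packaged `ClassProfile` transcribes
the published training-cohort descriptives: prevalences (0.75, 0.05, 0.16,
0.04) and per-class targets for 3 continuous variables (medians), 1 ordinal
(mean) and 8 binaries (proportions).

- **Class counts**: exact largest-remainder allocation of n·prevalence
  (multinomial draws optional).  At n=1066 this gives (799, 53, 171, 43),
  each within 2 of its quota — the observed cohort counts (800, 55, 169,
  42) are an empirical draw, not the allocation target.
- **Continuous** variables: log-normal with location ln(median) — the
  theoretical median is then exactly the target — and log-scale SD 0.5 (a
  choice: only medians were published; 0.5 gives right-skewed, strictly
  positive measurements with IQR/median ratios typical of tumor-diameter
  data).  Variables whose printed median is 0 (benign solid-part diameter)
  get a structural zero mass of 0.55 plus a log-normal tail (nonzero-median
  15 mm); 0.55 rather than 0.50 so the finite-sample median is robustly 0
  rather than a coin flip on the atom boundary.
- **Ordinal** papillation count: Poisson conditioned on {0..4}, rate solved
  so the truncated mean matches the published mean exactly.
- **Binaries**: Bernoulli at the published proportions.
- **Independence within class** is the honest default — the publication
  carries no correlation information — with the consequence that synthetic
  classes are *more* separable than real ones: the worked example's
  internal-validation polytomous c-index (~0.77) sits above the original
  study's (~0.67–0.69), and temporal/external degradation cannot be
  emulated.  A green end-to-end test therefore establishes that the
  machinery works and ranks sanely, not that clinical performance is
  reproduced.  A Gaussian-copula correlation hook is the natural extension
  and is out of scope.

All randomness flows through explicit integer seeds; identical seeds give
identical datasets, fits and reports.

## Known limitations

- The Bayesian LS-SVM output and the CI method are documented substitutes
  (see above), not reconstructions of the cited frameworks.
- R1U is linear-kernel only, matching its derivation.
- No missing-data handling: inputs must be complete.
- Center effects are carried as an optional stratification label only.
- The published models' coefficients are not reproducible because the
  clinical data are not deposited; the packaged variable lists reproduce
  the published model *structures* instead.
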