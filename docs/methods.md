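# Methods

This note records the statistical model, the algorithmic and numerical
choices, and the scope of what the synthetic-data tests demonstrate.

## Likelihood core

The data enter in summarized form {(x_i, Y_i), i = 1..m}: distinct
covariate rows x_i ∈ ℝ^d with multinomial count vectors
Y_i ~ Multinomial(n_i; π_i), independent across rows. With continuous
covariates every row is distinct and m = n. The multinomial coefficient is
omitted from the log-likelihood throughout: it is a constant of the data,
shared by all eight candidate models, so AIC *comparisons* are unaffected;
absolute log-likelihoods differ from implementations that include it by
that data-only constant.

The four links (baseline-category, cumulative, adjacent-categories,
continuation-ratio) are inverted with log-sum-exp stabilization. For the
cumulative link the probabilities π_j = γ_j − γ_{j−1} can leave the simplex
when the latent cumulative logits are not increasing; such vectors are
returned with negative entries so the fitter rejects the step — they are
never clipped during fitting. Prediction on new covariate rows may clip a
slightly negative cumulative probability to zero and renormalize, since no
likelihood is being optimized there.

**Fitting** is Fisher scoring. For each row the score with respect to η is
Jᵀ(Y/π) and the expected information is n_i Jᵀ diag(1/π) J, with J = ∂π/∂η
computed analytically per link; both are pulled back through the
main-effects design (po: p = J−1+d; npo: p = (J−1)(d+1)). A ridge of
10⁻¹⁰·(tr F/p + 1) keeps the solve well posed under quasi-separation. Step
halving accepts the first step that keeps probabilities valid and does not
decrease the likelihood, which makes the ascent monotone — the property the
iteration-cap behavior under separation relies on.

* Initialization: all parameters zero; cumulative-link intercepts start at
  the empirical cumulative logits of the marginal category frequencies so
  the initial iterate is valid.
* Convergence: stop when the per-iterate likelihood increase falls below
  `tol` (default 1e-8); `converged` requires the gradient norm to be below
  `gtol·(1+|loglik|)` (gtol default 1e-4).
* Separation: with informative covariates the likelihood supremum may not
  be attained (fitted probabilities → 1 at observed categories). The fitter
  caps iterations (default 30), reports the best iterate with
  `converged=False`, and raises `separation_flag` when fitted probabilities
  at observed categories exceed 1 − 1e-10 or the likelihood stalls with a
  non-vanishing gradient. No penalization is applied: the reported AIC
  under separation is an artifact of the stopping rule, which is why
  cross-validated cross-entropy, not in-sample AIC, is the model-selection
  loss across *different* links. Matching another optimizer's stopping
  point under separation is explicitly not promised.
* Feasibility: fitting requires m ≥ d+1 distinct rows (main-effects, both
  structures); below that the fit raises and points the user to screening.

Hard labels are the argmax of the predictive probability vector, ties to
the smallest category index, so results are deterministic.

## Candidate distributions and screening

The 12-family candidate set is normal, half-normal, log-normal and
exponential, each plain, zero-inflated and hurdle. For a continuous
baseline the zero-inflated and hurdle likelihoods coincide (the continuous
part puts no mass on {0}); both labels are retained so the set keeps its 12
members. All MLEs are closed form; φ̂ is the exact-zero fraction, with the
0·log 0 = 0 convention at the boundaries φ̂ ∈ {0, 1}. A family is
infeasible (log-likelihood −∞) iff some data point receives zero density —
e.g. plain log-normal on data with zeros, negative values under a
non-negative support, a degenerate (zero-variance) baseline, or fewer than
two nonzero values to fit a zero-mass family's baseline on. Infeasibility
is a flagged state, not an exception, so whole-matrix screening never
aborts.

**Goodness of fit.** The KS statistic is computed against the fitted
*mixed* CDF (jump of size φ at zero), with the right-continuous empirical
CDF and the fitted CDF evaluated from the left at the atom. Because the
parameters are estimated and the CDF has an atom, the classical KS null is
invalid; p-values use a seeded parametric bootstrap (default 200
replicates): resample from the fitted model, refit the same family,
recompute the statistic, report the exceedance proportion. A bootstrap
replicate on which the family is infeasible counts with statistic 1, which
can only inflate (conservatively) the p-value. `select_family` returns the
feasible fit with the largest p-value; ties break by larger log-likelihood,
then by the canonical 12-family order.

**Screening statistic.** Δ = AIC(I) − AIC(II), where model II's AIC is the
sum of per-group AICs with an independently selected family per group (a
config switch forces one shared family per gene, chosen to minimize the
summed AIC). The same derived sub-seed drives the model-I fit and every
per-group fit, which makes Δ exactly invariant to group relabeling and
makes the degenerate single-group case give Δ = 0 identically. The master
seed expands to per-covariate sub-seeds by column index, so rankings are
reproducible and order-independent. Sparsity-filter bounds are inclusive:
"between 5% and 50%" is read as [0.05, 0.50], the weaker assumption.

Δ is a ranking device, not a calibrated test statistic; no FDR control is
attempted across covariates.

## Selection layers

* **Working order.** Exhaustive search over all J! orders up to J = 8
  (40,320 fits); beyond that a user-supplied candidate list is required.
  Ties — including the structural reversal tie of the adjacent-categories
  po model — break to the lexicographically smallest permutation. Order
  search is offered for all three order-dependent links under po structure.
  For the baseline-category po model the analogous choice is the reference
  category (J fits); for npo structure both choices are irrelevant to the
  fit, and the code refuses to pretend otherwise.
* **Cross-validation.** Folds are an unstratified seeded partition of the
  original observations into K blocks whose sizes differ by at most one
  (the first n mod K blocks take the extra observation); the fold map is
  stored in the report for exact replay. A fold whose fit is infeasible
  poisons the whole (model, t) configuration with CE = +∞ rather than
  being dropped, so comparisons stay conservative. Stratified folding
  exists as an explicit off-by-default choice.
* **Covariate count.** CE(t) is evaluated on a grid (default
  {25, 30, 50, 60, 70, 80, 100, 150}, truncated to the available ranking)
  with one shared fold map across all configurations; ties prefer smaller
  t, then the given model order.
* **Backward elimination.** Strict-improvement rule: remove the covariate
  whose removal minimizes AIC while that minimum is below the current AIC;
  ties to the smallest column index. Candidate refits warm-start from the
  current fit with the removed covariate's coefficients dropped; a test
  verifies warm and cold starts agree on small instances. Forward and
  hybrid selection are out of scope.

The pipeline driver chains filter → rank → covariate-count CV → order
search (po finalists) → backward elimination → final CV, keeping the top
`n_finalists` models by CV cross-entropy. It is a pure function of (data,
config, master seed); rerunning writes byte-identical artifacts.

## Synthetic data generator

Two generative directions, because the two halves of the procedure condition
in opposite directions: `labels_first` draws labels from class
probabilities and then genes conditionally on the label (the screening
regime — informative genes have group-specific zero-inflated
distributions), while `logit_first` draws genes and then labels from a
known multinomial logit with a known working order (the regression regime —
full ground truth for recovery tests). Presets: `null` (no informative
genes, n = 400), `informative_zi` (5 informative + 20 null sparse genes,
n = 500, group φ in [0.05, 0.50]), `adjacent_po_truth` (adjacent-po truth
with order (1, 2, 0), n = 2000, d = 2), `binary_equivalence` (J = 2,
n = 100). Preset sizes keep the full suite around a minute on one CPU.

The generator emulates the *marginal* shape of sparse expression data —
non-negative, skewed, exact zeros at controlled rates — and none of its
read-level structure: no library-size variation, batch effects, gene–gene
correlation, or count overdispersion. Passing tests therefore demonstrate
the statistical machinery (likelihoods, invariances, selection rules,
recovery under the assumed models), not robustness to real RNA-seq
artifacts.

## Verification approach and problem sizes

Independent oracles back the main computations: closed-form MLEs are
checked against iterative grid refinement and Nelder-Mead on the same
likelihood; the Fisher-scoring optimum against a 50-start derivative-free
search on ten tiny instances (agreement to 1e-6); the grouped likelihood
against brute-force summation; backward elimination against exhaustive
best-subset enumeration at d = 8; cross-entropy against its closed forms
(log J for the uniform predictor, 0 for an oracle). Structural invariants —
npo order invariance, the adjacent-po reversal tie, the J = 2 collapse of
all eight models — are asserted at 1e-6/1e-8 on fixed datasets chosen to be
well conditioned (no separation), since the invariants hold at the exact
optimum and tight convergence is needed to observe them numerically.
Parameter recovery at n = 2000 is judged by the mean over 20 replicates
lying within 3 Monte-Carlo standard errors of the truth — the standard
simulation bias check; a single-draw 3-sigma criterion would fail for
roughly one seed in a hundred per parameter by construction.

Simulation sizes (n between 100 and 2000, up to 40 covariates, bootstrap
counts of 10–100 in tests) were chosen so the suite exercises every code
path in about a minute; the acceptance script uses n = 500, 25 genes,
100 bootstrap replicates and the full 120-permutation order search at
J = 5.

## Known limitations

* No standard errors or Wald intervals; the Fisher information is used only
  for scoring and feasibility.
* AIC values under quasi-separation depend on the iteration cap; only
  cross-validated quantities are stable across optimizers there.
* The bootstrap KS procedure is a documented substitute for whatever
  calibration an external screening implementation may use; p-values are
  Monte-Carlo estimates with resolution 1/n_boot.
* Covariate transformations and interactions are out of scope; all models
  are main-effects.
* Exhaustive order search is factorial in J and refuses beyond J = 8.
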