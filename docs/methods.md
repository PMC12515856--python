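# Methods

## Data model and edge indexing

A study is a stack of N symmetric M×M connectivity matrices with subject
identifiers, an outcome, and optional n×J numeric covariates. Edges are the
strict upper triangle in row-major order — E = M(M−1)/2 features, a stable
bijection between flat indices and node pairs for the whole run. The diagonal
(self-connections) never enters any computation. Symmetry is enforced to an
absolute tolerance of 1e-8 and violations are rejected rather than repaired
by averaging: an asymmetric input indicates an upstream preprocessing bug
that silent symmetrization would hide. Node indices are 0-based internally
and 1-based in every user-facing export, matching atlas conventions.

Whether connectivity weights should be Fisher-z transformed before modeling
is left to the user: the pipeline consumes whatever weights are supplied.

## Marginal screening

Each edge is tested alone against the outcome; edges with two-sided p
strictly below `thresh` advance, split by the sign of the statistic.
Strict inequality makes the `thresh = 1` semantics coherent: degenerate
(zero-variance) edges are assigned p = 1 and are therefore never selected,
while every other edge is (no preselection). No multiple-testing correction
is applied — the cutoff is a raw per-edge p-value.

- Pearson (default) and Spearman p-values use the t transform
  t = r·√((n−2)/(1−r²)) with n−2 df (Spearman on ranks); Kendall uses the
  tau-b normal approximation. The default method is Pearson; Spearman and
  Kendall are offered for monotone-but-nonlinear associations and for
  binary/categorical outcomes, which are coded 0..L−1 in declared level
  order. For nominal categories this coding is order-dependent; there is no
  canonical ordering for rank correlation against arbitrary codes, so the
  convention is documented rather than hidden. n ≥ 4 is required.
- Survival outcomes use a univariate Cox fit per edge: Newton–Raphson run
  vectorized across all edges simultaneously on standardized columns (the
  Wald z is scale-invariant; coefficients are rescaled afterwards), with the
  Wald p from the observed information. At least 2 events are required.

## Design construction and penalty exemption

The original arm sums selected edge weights per subject — a_pos and a_neg for
the signed sets, or one combined sum over the union. The sum (not the mean)
is used; the two differ by a constant factor per set, which the downstream
regression slope absorbs. Note that the combined sum adds positively and
negatively associated edges without sign distinction, so mixed-sign signal
can cancel in that mode — the separate mode is the safer default.

The penalized arm keeps the selected-edge block A (n×K). Either way the
design is X* = [A | X] with a penalty mask that is 1 exactly on edge columns.
The intercept lives in the model layer and, like the covariates, is never
penalized, screened, or dropped.

An empty selected set is not an error: the fold falls back to a
covariate-only model (or the training marginal when there are no covariates)
and is flagged.

## Models

**GLMs** (gaussian/identity, binomial/logit, multinomial logit against a
reference level — the first declared factor level, for determinism) are
fitted by Newton–Raphson with step halving, which keeps the log-likelihood
non-decreasing across iterations; convergence is max|Δβ| < 1e-8 within 100
iterations. The gaussian case uses least squares directly. Rank-deficient
designs raise with a pointer to the penalized arm; complete separation in
logistic fits surfaces as a flagged non-convergence with a warning. Hard
labels use a 0.5 probability threshold (binary) or argmax with ties broken
toward the lowest class index (multinomial); the AUC metrics consume
probabilities, so labeling conventions affect nothing measured.

**Cox** models maximize the Breslow-approximated log partial likelihood by
Newton–Raphson with step halving (|Δ logPL| < 1e-9, ≤ 50 iterations). The
risk set is right-continuous (subjects with time equal to the event time are
at risk). The no-ties assumption common in theory is relaxed to Breslow's
approximation because real follow-up times are routinely tied. Monotone
likelihood (perfect risk separation) is detected by a per-standard-deviation
effect exceeding 10 on the log-hazard scale and flagged as non-convergence.
No baseline hazard is estimated: predictions are linear predictors, which is
all the C-index needs. Deaths without the event of interest are treated as
right-censoring, not competing risks — users with substantial competing
mortality should be aware of the difference.

## Penalized estimation

All four families minimize

    (1/n)·NLL(β₀, β) + λ·[ (1−α)‖β_A‖₁ + α‖β_A‖₂² ]

with the penalty restricted to edge coefficients β_A. The α orientation
follows the constraint form with α = λ₂/(λ₁+λ₂): **α multiplies the squared-L2
term**, which is the reverse of the glmnet convention. Hence α = 0 is the
pure lasso, α = 1 the pure ridge, and the endpoint equivalences are exact
(tested to 1e-8). The default α = 0.95 is therefore L2-dominant; users
wanting near-lasso behavior under this convention should set α near 0.
`type="lasso"`/`"ridge"` pin the penalty regardless of α. The 1/n loss
scaling fixes the λ scale and makes the path invariant to row duplication.

The solver is cyclic coordinate descent with active-set iteration
(tolerance 1e-7 on coefficient updates). Penalized columns are standardized
to unit variance internally so the penalty treats edges of unequal scale
fairly; coefficients are reported on the original scale; exempt covariates
are not standardized. Non-gaussian families wrap the coordinate descent in
iteratively-reweighted least squares (outer tolerance 1e-6): logistic uses
the canonical weights μ(1−μ), multinomial cycles per-class quadratic
approximations of the reference-parameterized likelihood, and Cox uses the
Breslow score with a diagonal Hessian approximation. Weights are floored at
1e-5 to avoid degenerate working responses.

λ selection: an automatic path of 100 log-spaced values from λ_max (the
smallest λ that zeroes every edge coefficient, computed from the score of the
covariate-only fit; the L1 weight is floored at 1e-3 so a pure ridge penalty
still gets a finite path) down to λ_max·1e-4 (1e-2 when n ≤ K+J). The chosen
λ minimizes the mean held-out deviance over inner cross-validation folds
(10 by default, stratified by class or event status), with ties going to the
larger λ. The minimum-deviance rule (no one-standard-error rule) is the
simplest deterministic reading of "automatically searched". Inner folds with
degenerate outcomes are skipped with a warning; if all are degenerate the
selection errors out.

## Cross-validation and leakage

Folds are assigned deterministically from the seed; sizes differ by at most
one; leave-one-out is k-fold with k = n. Binary/categorical outcomes are
stratified by level and survival outcomes by event status (on by default,
switchable off) so inner fits rarely see single-class folds. Screening,
summary construction, λ selection, and model fitting all happen strictly
inside each training fold; the held-out subjects only ever receive
predictions. This is asserted by a test that perturbs a held-out subject's
connectome and checks the fold's selection is unchanged. External validation
refits once on the full training cohort and predicts the external set;
fitted models are exposed only on this path.

## Evaluation

Pearson r + MSE (linear), Mann–Whitney AUC on probabilities (logistic),
macro-averaged one-vs-rest AUC (multinomial; macro because the one-vs-rest
prescription does not fix a weighting, and the unweighted mean is the
simplest), and Harrell's C-index (Cox; permissible pairs are those whose
earlier time belongs to an observed event, predictor ties count ½). Ties in
AUC count ½. The primary report pools held-out predictions across folds —
every subject appears exactly once — and per-fold metric distributions are
also emitted, since either convention appears in practice.

## Consensus edges and network aggregation

An edge enters the consensus when selected in at least ⌈fold_threshold·K⌉ of
K folds. The threshold is a fraction in (0, 1]; the count rule with the
ceiling makes 0.5 mean "at least half the folds" exactly and keeps the
parameter independent of K. Its sign is the majority sign across folds; ties
are excluded with a warning. For lasso/elastic-net penalized runs "selected
in a fold" means a nonzero fitted coefficient; for ridge (which never zeroes
coefficients) and for the original arm it means passing marginal screening.
Consensus edges are counted per unordered network pair into two symmetric
L×L matrices (positive/negative), within-network edges on the diagonal, so
the matrix total equals the retained-edge count (asserted). The heatmap uses
a red gradient for positive counts and blue for negative, and the mean
screening statistic per cell is exported alongside for intensity-based
coloring.

The bundled 268-node → 10-network table is a **synthetic stand-in** with the
Shen268 atlas shape (268 nodes, the 10 canonical network labels, plausible
block sizes); the published per-node assignment is external data and is not
redistributed here. All structural behavior is faithful; users analyzing
real Shen268 connectomes should supply the published table as a CSV.

## Synthetic studies

The generator emulates the shapes of a real study: edge weights drawn
independently as N(0, 0.3) clipped to [−1, 1] (FC-like), an age-like and a
binary sex-like covariate (effect 0.5 each by default), and a latent score
s = effect_size·(Σ positive-signal − Σ negative-signal edges) + covariate
term driving the outcome. Gaussian outcomes add N(0, σ) noise with σ matched
to the signal spread by default (R² ≈ 0.5, a realistic ceiling for
connectome prediction); binary outcomes are Bernoulli through the logit;
categorical outcomes sample a softmax over per-class scores with slopes
spread over [−1, 1]; survival times are exponential with hazard exp(s)
(proportional hazards exact by construction) under independent uniform
censoring whose upper bound is solved numerically to hit the target
censoring fraction (default 0.3, typical of observational cohorts).

Independence across edges makes false-positive calibration exact (the null
edge-selection rate at cutoff p equals p); an optional block-correlation mode
adds shared latent factors for stress testing. What the generator does *not*
emulate: spatial autocorrelation of real connectomes, site/scanner effects,
heavy-tailed motion artifacts, and covariate–edge confounding. Passing tests
therefore demonstrate correctness of the machinery and calibration under
idealized noise, not field performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run on simulated studies of
n = 60–200 subjects and M = 8–20 nodes (E ≤ 190 edges), with 10-fold outer
and 4–10-fold inner cross-validation — sizes at which every property of
interest (calibration, recovery, leakage, oracle agreement) is already
measurable while the whole suite stays interactive. Degenerate inputs are
handled as described above (flagged fallbacks, warnings, or errors naming
the offending subject/cell). All randomness flows through explicit seeds;
identical configuration and seed reproduce bit-identical results.

## Known limitations

- No ordinal logistic regression (categorical outcomes are treated as
  nominal), no time-varying covariates, competing risks, or proportionality
  diagnostics, no FDR/permutation screening, no group lasso, and no nested
  search over `thresh`/α — these are per-run user choices.
- The penalized Cox solver uses a diagonal Hessian approximation; extreme
  collinearity among selected edges can slow outer convergence.
- Fold-consensus counts depend on K; compare runs at equal K.
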