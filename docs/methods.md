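# Methods

## Measurement model

`mdcat` measures four correlated latent traits — demoralization, anxiety,
irritability, depression — with a simple-structure multidimensional graded
response model (GRM). Item *j*, loading on trait *f(j)* with *K_j* ordered
categories, has cumulative response curves

    P(X_j ≥ k | θ) = σ(a_j θ_f(j) + d_jk),  k = 1..K_j−1,

with σ the logistic function, slope a_j > 0 (logistic metric, no 1.7
constant) and strictly decreasing intercepts d_j1 > … > d_j,K_j−1.
Category probabilities are adjacent differences of the cumulative curves.
Traits live on the standard-normal metric with correlation matrix Σ;
θ = 0 is the population midpoint, which is also the screening cut.

Cross-loadings, testlets and nominal/partial-credit parameterisations are
out of scope by design: the bank combines four unidimensional instruments,
one factor each.

## Scoring

The operational estimator inside the adaptive loop is the posterior mode
(MAP) under the N(0, Σ) prior. The log-posterior is strictly concave
(log-concavity of logistic CDF differences plus a positive-definite
quadratic prior), so the mode is unique; it is found by L-BFGS-B from a
warm start (the previous step's estimate), with an exact-Hessian Newton
polish and two deterministic random restarts as fallbacks. Convergence
means projected-gradient infinity-norm < 1e−6. Standard errors are
square-rooted diagonals of the inverse of

    posterior information = Σ⁻¹ + Σ_administered I_j(θ̂),

where I_j is the *expected* Fisher information of item j evaluated at the
mode (rank-one under simple structure). Expected rather than observed
information keeps selection and stopping response-independent, which is
how determinant-style selection rules are defined. An EAP estimator
(posterior mean by quasi-Monte-Carlo integration over ≥1000 Halton nodes)
is provided as a cross-check only; on well-conditioned 20+-item response
sets it agrees with MAP to within 0.15 per coordinate.

Numerical guards: θ clamped to [−6, 6], category probabilities floored at
1e−300. Neither affects any reported quantity at printed precision.

## Calibration (QMC-EM)

`fit_grm` maximises the marginal likelihood by EM:

* **Nodes.** A scrambled Halton sequence in [0,1)⁴ is mapped through the
  inverse-normal transform, affinely standardised to exactly zero mean and
  identity covariance, and rotated by the Cholesky factor of the current
  Σ. Standardisation matters: the node set's finite-sample covariance bias
  otherwise re-enters the Σ update every sweep and the slopes drift by a
  constant factor per iteration instead of converging. Default 5000 nodes
  (tests use 500–1500 for speed; the difference is in the third decimal).
* **E-step.** Per-person posterior weights over the nodes (equal prior
  weights, likelihood-proportional posterior). Missing responses simply
  contribute no terms (full-information treatment).
* **M-step.** Per item, a weighted ordinal-logistic maximisation by
  L-BFGS-B in an unconstrained parameterisation (log-slope, first
  intercept, log-gaps) that enforces positivity and intercept ordering.
  Σ is updated from posterior second moments and rescaled to unit
  diagonal, with the compensating (likelihood-invariant) rescale of the
  slopes; factor variances are therefore 1 by construction.
* **Acceleration.** A safeguarded Ramsay-style extrapolation of the item
  parameters: multiplier r/(1−r) from the ratio r of successive step
  norms, capped at 5; if the observed log-likelihood drops by more than
  1e−3 the step is rolled back and acceleration pauses for two sweeps.
* **Convergence.** Maximum absolute parameter change < 1e−4 (cap 500
  iterations). Empty observed categories are collapsed with a logged
  remap before fitting.

With fixed Σ and no acceleration the algorithm is exact EM on a finite
mixture and the log-likelihood trace is monotone to numerical precision;
with Σ free the trace is monotone up to small quadrature-drift terms
(bounded by the acceleration safeguard at 1e−3).

**Local independence.** Q3 is the Pearson correlation matrix of item
residuals x_pj − E[X_j | θ̂_p] with per-person MAP estimates; pairs with
|Q3| ≥ 0.50 are flagged, report-only. Q3 carries the usual negative
conditioning bias, roughly −1/(m−1) scaled by estimate reliability for m
same-factor items: with only 4 items per factor the worst within-factor
pair can exceed 0.3 in absolute value under exact local independence, so
null-behaviour checks are run on the full 44-item bank, where the bias
stays well below the 0.50 flag.

Global limited-information fit indices (M2, RMSEA, CFI/TLI, SRMSR) and
S-X2 item fit are intentionally not implemented: they are only meaningful
against real data that the package does not ship.

## Adaptive engine

A session runs start → administer → re-score → stopping check → select →
administer → …, with the trajectory recording the prior state first.

* **Start.** Fixed item `demo18` by default; an adaptive alternative
  (maximum DP determinant at θ = 0) is available by configuration.
* **Selection.** DP (default): argmax_j det(Σ⁻¹ + Σ_administered I_i(θ̂)
  + I_j(θ̂)), all information evaluated at the current mode. D: the same
  without Σ⁻¹. KL: the Kullback–Leibler divergence between the response
  distributions at θ̂ and at nearby trait values, integrated over a
  ‖θ′−θ̂‖∞ ≤ δ box (δ = 0.1, 11-point grid per dimension; under simple
  structure the integrand varies only along the item's own factor, so the
  box integral reduces to a one-dimensional grid average times the common
  box volume). KLn: δ scaled by √n administered. random: uniform.
  Ties break on the lowest bank index.
* **Exposure control.** Randomesque: scores are multiplied by per-item
  exposure weights, then one of the top-m ranked candidates is drawn
  uniformly (m = 1 by default, i.e. off). One seeded generator drives both
  response simulation and exposure draws, so sessions replay exactly.
* **Stopping.** Stop iff (n ≥ 4 AND [every SE ≤ its threshold OR the max
  coordinate change of θ̂ since the previous item < 0.01]) OR n ≥ 25.
  The Δθ clause activates only at the minimum length and compares
  strictly; the precision clause wins ties in the recorded reason. The
  shipped default configuration is: start `demo18`, DP rule, SE
  thresholds (0.45, 0.50, 0.50, 0.45) in (demoralization, anxiety,
  irritability, depression) order, Δθ = 0.01, length 4–25. Stopping with
  the SE and Δθ clauses disjunctive ("either ends the test") is a design
  choice; the min-length guard prevents the Δθ clause from firing on the
  prior alone. `bank_exhausted` is recorded when a configuration allows
  more items than the bank holds.

## Synthetic bank and cohorts

The generator emulates the screening battery's structure: 24 demoralization
and 6 anxiety items on 0–4 scales, 5 irritability items on 0–4, 9
depression items on 0–3. Factor correlations default to the published
estimates (demoralization–depression 0.93, anxiety–irritability 0.759,
demoralization–anxiety 0.671, demoralization–irritability 0.526,
irritability–depression 0.498); the anxiety–depression entry is never
published and defaults to 0.60, near the value implied by the two factors'
shared correlation with demoralization — it is a package default, not an
observed quantity. The matrix is checked for positive definiteness
(smallest eigenvalue 0.064 at the defaults).

Category boundaries b_1 < … < b_{K−1} are sorted draws from N(0.4, 1),
then d_k = −a·b_k: the positive centre skews items toward low endorsement,
as clinical symptom scales typically behave (extreme categories
infrequent). Slope ranges are uniform per factor — (1.4, 2.8) for
demoralization, (1.6, 3.2) for anxiety, (1.1, 2.4) for irritability and
depression — chosen so each instrument's marginal reliability (1 − mean
posterior variance from its own items under a univariate normal prior)
matches the published internal consistencies 0.94 / 0.85 / 0.82 / 0.83 to
within 0.03 (measured: 0.954 / 0.849 / 0.805 / 0.847). Virtual respondents
are drawn from N(0, Σ).

What the generator does **not** emulate: real item wording effects, local
dependence, differential item functioning, response styles, missingness
mechanisms, and — importantly — the true discriminations of the original
instruments, which are unpublished. Passing simulation tests therefore
demonstrate the engine's internal consistency under a
reliability-anchored bank, not the operating characteristics of the
clinical instrument.

### What precision-based stopping implies for recovery

With a correctly specified Bayesian scorer, marginal recovery is governed
by the SEs at stop: RMSD² ≈ E[SE²] and corr ≈ √(1 − RMSD²). Stopping at
SE thresholds of 0.45/0.50 therefore places recovery near corr 0.87–0.92
and RMSD 0.40–0.50 on this bank — the adaptive runs in this package land
exactly there (per-factor correlations ≈ 0.87–0.94, RMSD ≈ 0.36–0.49,
mean length ≈ 10.3, median 9, range 4–25, on 1000 respondents). Recovery
beyond that would require items informative enough that the minimum test
length overshoots the precision targets, which the reliability anchor
precludes. The headline-comparison tests encode the published summary
values and are allowed to fail; the simulation report itself is the
package's honest characterisation of the configuration.

## Criterion validity and screening output

A domain's warning fires when θ̂ > 0 strictly ("exceeds the midpoint");
the continuum position for display is Φ(θ̂). Discrimination against a
binary gold standard uses the tie-corrected rank (Mann–Whitney) AUC —
chosen over trapezoidal ROC integration so the O(n²) concordance oracle is
exact — and the 2×2 table at a stated threshold with predicted positive =
score > threshold. Single-class label vectors raise an error that still
carries the completed table. The synthetic gold labels produced by
`make-fixtures` are Bernoulli(Φ(1.2·θ_demoralization − 0.4)) draws: a
synthetic stand-in for an interview diagnosis, yielding ~30% prevalence
and a strong but imperfect score–diagnosis association.

## Problem sizes and defaults

| Quantity | Default | Notes |
| --- | --- | --- |
| QMC nodes (calibration) | 5000 | tests use 500–1500 |
| EM tolerance / cap | 1e−4 / 500 | max absolute parameter change |
| MAP gradient tolerance | 1e−6 | projected infinity-norm |
| KL box δ / grid | 0.1 / 11 points | configurable |
| Simulation cohort | 1000 | drawn from N(0, Σ) |
| Bank seed | 20240101 | fixed study condition |

Deterministic replay holds end to end: every stochastic entry point takes
a seed, per-respondent generators are spawned from a seed sequence, and
identical seeds reproduce sessions, fits and reports bit-identically.
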