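# Methods

## The estimand and estimator

For two arms with category distributions π⁽¹⁾, π⁽²⁾ over K ordinal DOOR
levels (level 1 most desirable), the DOOR probability is

p = Σ_k π⁽¹⁾_k ( Σ_{j>k} π⁽²⁾_j + ½ π⁽²⁾_k ),

the probability that a random experimental participant's outcome is more
desirable than a random control participant's, ties counted half. The
estimator replaces π by empirical proportions, equivalently

p̂ = (W + T/2)/(n₁n₂),  W = Σ_k a_k Σ_{j>k} b_j,  T = Σ_k a_k b_k,

with a, b the per-arm category counts. `count_pairs` evaluates this closed
form; the test suite verifies it against a brute-force loop over all
n₁×n₂ expanded pairs on hundreds of random tables. Direction symmetry
(p̂(A,B) + p̂(B,A) = 1), the net treatment benefit identity ntb = 2p̂ − 1 and
win-odds identity p̂/(1−p̂) hold exactly and are asserted as properties.

## Variances and confidence intervals

Two variance estimators are implemented.

* **Tie-corrected rank variance** (used by the primary interval and the
  test): var₀(p̂) = (N+1)/(12 n₁n₂) · [1 − Σ_j (t_j³−t_j)/(N³−N)], with t_j
  the combined-sample tie-group sizes and N = n₁+n₂. This is the exact
  variance of p̂ under arm exchangeability with the observed tie pattern.
* **Consistent U-statistic variance** (`variance_u`): the structural-
  component (DeLong-type) estimator S₁₀/n₁ + S₀₁/n₂ from the per-category
  placement probabilities, consistent under arbitrary alternatives. A
  within-arm bootstrap at 10,000 replicates agrees with it within 10%
  relative error in the tests, and it scales as 1/n.

The primary interval (`halperin_ci`, default `tie-corrected-logit`) is
symmetric on the logit scale: logit(p̂) ± z·√var₀/(p̂(1−p̂)), back-
transformed and clipped to [0,1]. The logit transform keeps bounds inside
(0,1) and matches the asymmetry that probability-scale intervals near the
boundaries require. This choice was calibrated against the published
analyses shipped as the package fixture: it reproduces every printed bound
(overall and both significant components) to 0.1 percentage point, which a
Wald interval on the consistent variance does not (it misses one component
upper bound by 0.06 points). A labeled `logit-wald` fallback on
`variance_u` is provided for contrasts far from p = ½, where the
exchangeability variance is not the sampling variance. Under identical
multinomial arms at n = 100/arm, empirical coverage of the default
interval is within [0.93, 0.97] (2,000 replicates, seeded, asserted).

The WMW test uses z = (p̂ − ½)/√var₀, no continuity correction by default
(a flag enables it); it agrees with the asymptotic tie-corrected
Mann–Whitney test in scipy to 10 significant digits on random tables, and
its type-I error at α = 0.05 lies in [0.035, 0.065] in the seeded null
simulation. Degenerate tables (every participant in one category) return
p-value 1 and a collapsed interval, with warnings.

## Partial credit

Mean grades are linear functionals of the category proportions, so the
between-arm difference for a key with grades g is Σ_k (a_k/n₁ − b_k/n₂) g_k
— affine in each grade with slope a_k/n₁ − b_k/n₂. Inference uses the
unpooled-variance normal comparison of means; the grade-grid sweep
therefore vectorizes exactly (no per-cell refitting), and the grid is
checked cell-by-cell against the scalar estimator. The default grid is
1-point steps over [0,100]² (101×101) for the two free interior levels;
remaining interior levels must be fixed explicitly, since no convention
exists for them. Non-monotone cells are computed and flagged rather than
dropped: the sweep intentionally covers the full square. "Favored" status
requires both sign and two-sided p < α (default 0.05); the tipping
boundary is emitted as marching-squares cell-edge segments on the favored
matrix, which is resolution-independent and directly plottable. Note the
boundary is generally *not* the diff = 0 locus: the standard error varies
over the grid, so the significance frontier curves even when the contrast
depends on one grade only.

## Standardized gain/loss

Per-category expected gain/loss per N treated is (a_k/n₁ − b_k/n₂)·N,
rounded half away from zero to whole patients, computed from raw counts
(never from rounded percentages); cumulative values use cumulative
proportions. Pre-rounding per-category values sum to zero whenever both
arms are fully classified. The default standard cohort is N = 1,000.

## IPTW weighting

Stabilized weights are P(exp)/e for experimental participants and
(1−P(exp))/(1−e) for controls, with e the supplied propensity score and
P(exp) the empirical marginal. Propensity estimation is deliberately out
of scope — scores are inputs — so the package stays agnostic to the
propensity model. Weighted pair tallies replace counts by per-category
weight sums; the weighted DOOR probability is invariant to rescaling all
weights and reduces exactly to the unweighted estimator at unit weights
(asserted). Confidence intervals use a stratified (within-arm)
nonparametric bootstrap, percentile method, default B = 2,000, seed
required; bootstrap replicates that leave an arm weightless are dropped.
Weight truncation is off by default (0/100 percentiles) and configurable.

## Synthetic data

The generator emulates a two-arm trial with an event-count DOOR outcome:
category 1 = alive with no events, category k = alive with k−1 deleterious
events, category K = death. Component flags are drawn *from* the category
(exactly k−1 non-fatal flags set, chosen by weighted sampling without
replacement), so flags never contradict the category; death sets only the
death flag. Arm distributions are multinomial; all draws are seeded.

The confounded scenario adds a single binary severity covariate
(prevalence 0.5) that shifts treatment assignment toward the experimental
arm and every cumulative log-odds of the outcome toward less desirable
categories by the same amount (`effect`). True propensities are recorded.
The packaged scenario uses effect = 2.0 — strong severity confounding of
the kind that motivates weighting in observational comparisons — and a
true treatment benefit of 0.3 on the cumulative log-odds. The marginal
truth (mixture of covariate-conditional distributions under each
counterfactual assignment) is computed in closed form: 0.538, versus an
unweighted asymptotic value of 0.412 from the conditional-on-arm
mixtures — a bias of −0.13 that dwarfs sampling error at n = 1,000. The
recovery test requires the weighted estimate to beat the unweighted one in
≥ 95% of 1,000 replicates.

What the generator does **not** emulate: covariate-dependent missingness,
measurement error in components, multiple or continuous confounders,
non-proportional-odds covariate effects, and event timing. Passing tests
therefore demonstrate estimator correctness under a clean
proportional-odds single-confounder world, not robustness to model
violations in real observational data.

## Design-stage power

The true DOOR probability of a scenario is the closed form above; power
for the two-sided tie-corrected WMW test is the rejection fraction over
seeded multinomial trial simulations (default 2,000), with a Wilson
Monte-Carlo interval. Sample-size search bisects over n using common
random numbers — one per-patient category stream per simulation, trials of
size n formed from the first n patients — which makes estimated power
nondecreasing in n and the search reproducible. At very small n the
discrete test cannot reject at all (|z| ≤ √3 at n = 2/arm), so the
smallest achievable n for any positive target power is where rejection
first becomes possible. Defaults α = 0.05, target power 0.90 are package
conventions.

## Numerical choices and limitations

* Ties always receive weight ½; no alternative tie rules are exposed.
* Category index 1 is always the most desirable; arm order is
  (experimental, control) and all contrasts are experimental − control.
* Reported probabilities render as percentages to one decimal.
* Only two-arm contrasts are supported; no time-to-event ("sliding")
  DOOR, no group-sequential monitoring, no meta-analysis, no multiplicity
  adjustment across components by default.
* The exact-permutation WMW p-value is not implemented; the normal
  approximation with tie correction is accurate at the sample sizes DOOR
  trials use, but small-n exact inference is out of scope.
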