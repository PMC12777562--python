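# doorstat

Rank- and grade-based benefit:risk analysis of ordinal **DOOR** outcomes
(desirability of outcome ranking) in two-arm clinical studies.

Trials usually analyze efficacy and safety outcomes one at a time, which
hides how benefits and harms combine in individual patients. A DOOR outcome
instead ranks each participant's *overall* experience on an ordinal scale
ordered from most desirable (e.g. "alive with no events") to least
desirable (death). `doorstat` implements the statistical toolkit for
analyzing such outcomes: it is written for trial statisticians and clinical
researchers who need the full analysis — estimate, interval, test,
tabular summaries, sensitivity sweeps, weighting for nonrandomized
comparisons, and design-stage power.

## The statistics

**DOOR probability (rank-based).** With n₁ participants on the experimental
arm and n₂ on the control arm, every one of the n₁×n₂ cross-arm pairs is a
win, a tie, or a loss for the experimental participant, and

> p̂ = ( #[more desirable] + ½·#[ties] ) / (n₁·n₂),

the Wilcoxon–Mann–Whitney win probability with half-weight ties. p = 50%
means no difference; p > 50% favors the experimental arm. For ordinal data
the pair loop collapses exactly to a closed form over the 2×K count table.
Confidence intervals are symmetric on the logit scale with the
combined-sample tie-corrected rank variance; hypothesis tests use the
tie-corrected normal-approximation WMW statistic. Win ratio
(wins/losses), win odds (p/(1−p)) and net treatment benefit (2p−1) are
derived from the same pair tallies. Binary component outcomes and
cumulative dichotomies ("top k categories vs rest") are analyzed as
2-level DOOR outcomes on the same footing.

**Partial credit (grade-based).** A grading key assigns each category a
grade: 100 for the best category, 0 for death, partial credit in between.
The contrast is the difference in mean grades, tested with an
unpooled-variance normal comparison. Sweeping two interior grades over
[0,100]² maps which grading keys favor which therapy; the *tipping
boundary* separates the regions — a built-in robustness analysis.

**Standardized summaries.** The gain/loss table converts between-arm
differences in category proportions into expected patients gained or lost
per category per 1,000 treated — the absolute-risk scale on which
multiple outcomes are interpretable simultaneously.

**IPTW weighting.** For observational comparisons, stabilized
inverse-probability-of-treatment weights (built from user-supplied
propensity scores) reweight the pair tallies and grade means; confidence
intervals come from a seeded stratified bootstrap.

**Design.** The true DOOR probability implied by two category
distributions has a closed form; power for the WMW test is simulated, and
sample-size search bisects over n with common random numbers.

## Worked example

The packaged fixture holds the arm-by-category counts of a randomized
cUTI/pyelonephritis trial (doripenem vs levofloxacin, 374 per arm)
classified by a 5-level DOOR outcome (alive with 0/1/2/3 deleterious
events, death):

```python
import doorstat as ds

table = ds.load_fixture("dori05_door")
est = ds.halperin_ci(table)
print(est.as_percent_text(), f"P = {est.p_value:.2f}")
# 51.0% (47.6%, 54.3%) P = 0.58

gl = ds.gain_loss(table, standard_n=1000)
print(gl.per_category)   # (27, -48, 19, 0, 3)

for name, comp in ds.load_fixture("dori05_components").items():
    print(name, ds.component_door(comp).as_percent_text())
# Absence of clinical success 54.3% (51.1%, 57.4%)
# Infectious complications 47.6% (46.2%, 49.0%)
# Non-fatal SAEs 48.5% (46.9%, 50.1%)
# Death 49.9% (49.6%, 50.1%)
```

Read: the probability that a doripenem patient has a more desirable
overall outcome than a levofloxacin patient is 51.0% — no significant
overall difference (P = 0.58) — even though the efficacy component
significantly favors doripenem (54.3%) and the infectious-complications
component significantly favors levofloxacin (47.6%). Per 1,000 patients
treated with doripenem instead of levofloxacin, an expected 27 more end
"alive with no events", 48 fewer with exactly one deleterious event, and 3
more die. The DOOR analysis shows the benefit:risk trade-off that siloed
component analyses cannot.

The same analyses run from the shell:

```sh
door analyze config.yaml --out run1/     # tables, forest plot, estimates
door grid gridcfg.yaml   --out run2/     # partial-credit contour + tipping boundary
door power scenario.yaml                 # simulated power / sample size
door simulate spec.yaml  --out sim.csv   # synthetic patient-level trials
```

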