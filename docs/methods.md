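# Methods

## Effect sizes

Each two-arm study contributes, per outcome, the standardized mean difference
`g = (ȳ_med − ȳ_ctrl)/s_pooled` with the pooled SD computed from both arms'
variances, multiplied by the small-sample bias correction
`J = 1 − 3/(4(n_med + n_ctrl) − 9)`. The sampling variance uses the standard
large-sample form `(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))` — the default in
mainstream meta-analysis software; no variance formula is uniquely implied by
summary data, and this choice only enters through the pooling weights.

Sign conventions: for cue-induced craving and all drinking-quantity outcomes,
medication-minus-control, so a negative d favours the medication. Percent
days abstinent is scored in the opposite direction and is therefore computed
control-minus-medication; the flip is recorded per row (`sign_flipped`).
Drinking outcomes amalgamate into two composite endpoints — *heavy drinking*
(return to heavy drinking, percent heavy drinking days, drinks per
week/day/drinking day) and *abstinence* (return to any drinking, percent days
abstinent).

Crossover studies reported only as condition-level means/SDs are treated as
independent arms (no within-subject correlation is recoverable); they are
flagged `crossover=True` so sensitivity analyses can exclude them. Binary
relapse outcomes enter as pre-computed `(d, SE)` rows — there is no single
canonical binary→d conversion, so none is imposed.

## Pooling

Within medication × endpoint, effects pool by random-effects meta-analysis
with the DerSimonian–Laird moment estimator of between-study variance,
truncated at zero and fixed at zero when k = 1. Weights are `1/(vᵢ + τ²)`;
the pooled SE is `(Σwᵢ)^(−1/2)` with no Knapp–Hartung adjustment. Every
outcome-level effect size is pooled as an independent unit — k counts effect
sizes, not trials — and within-trial correlation between multiple outcomes
is ignored (no robust-variance or multilevel structure), a simplification to
keep in mind when interpreting pooled SEs.

## Errors-in-both-variables regression

With one `(d, SE)` pair per medication on each axis — craving on x, an RCT
endpoint on y — the line is estimated by Williamson–York weighted least
squares: minimize

    S(a, b) = Σᵢ (yᵢ − a − b xᵢ)² / (syᵢ² + b² sxᵢ²),

i.e. York's formulation with zero error correlation between axes. Solutions
satisfy the classic fixed point of the slope update; standard errors follow
York's (2004) adjusted-point expressions.

**Non-convexity and branch selection.** Because the weights depend on b, S
is non-convex. On the packaged nine-medication datasets it has exactly two
local minima of opposite sign (heavy drinking: −1.248 and +0.255, the
negative one global; abstinence: −0.776 and +0.825, likewise). The negative
branch is a steep line dominated by the two medications whose craving effects
have the most extreme values; the positive branch is the shallow line
weighted toward the precisely measured medications. `wy_fit` therefore makes
branch choice explicit:

* `select="global"` (default) — scan the profile objective S(b) over
  b = tan θ, refine every bracketed minimum, return the global one;
* `select="positive"` — the positive-slope local minimum when one exists
  (falling back to global), tracking the branch consistent with the
  directional hypothesis that craving suppression transfers to clinical
  benefit. The reference analysis reported exactly this branch, and the
  pipeline uses it;
* `select="init"` — plain fixed-point iteration from a starting slope
  (tolerance 1e−12 on successive slopes, max 200 iterations), tracking
  whatever solution that basin holds.

That the reported slopes sit on a non-global branch is a real sensitivity of
these data, not a numerical footnote: under `select="global"` both endpoint
slopes are negative. Documented here so users can probe both branches.

**Standard errors and inference.** Two SEs are reported. `se_slope_raw` is
the analytic York value, correct when the per-point errors are the true
noise scales. `se_slope` expands it by `√(S/(n−2))` (reduced chi-square), the
usual guard when stated errors may not capture all scatter; on published
pooled estimates this is the appropriate, more conservative choice, and the
Wald test (one-sided upper-tail normal `z = β̂/se_slope`, screening cut-off
1.64, corrected α = 0.05/2 = 0.025 for the two endpoint models) uses it. On
the packaged data: heavy drinking β̂ = 0.255, SE = 0.190, p = 0.090;
abstinence β̂ = 0.825, SE = 0.740, p = 0.133 — neither significant.

## Monte Carlo power

Per replicate, each medication's RCT effect size is drawn from
`N(a + b·xᵢ, syᵢ)` at the observed craving values (held fixed, as are all
SEs), the line is refitted warm-started at the generating slope, and a
rejection is scored when `z > 1.64`. Inside the simulation the stated errors
*are* the noise scales, so z uses the raw York SE; with the expanded SE the
statistic is t-like at n = 9 and anti-conservative. 10,000 replicates by
default; non-convergent refits (rare, ~0.1%) count as non-rejections.
Measured at the fitted lines: ≈0.97 for heavy drinking, ≈1.00 for abstinence.

Calibration caveat: with measurement errors on x as large as the spread of x
itself — which is the situation of the packaged craving data, SEs 0.077–0.541
against a spread of ~0.2 — the slope estimate is heavy-tailed and the test
rejects a true null in ~11% of replicates at nominal 5%. With modest x-errors
the test is nominal (measured 0.051 at 5,000 replicates). Power numbers on
these data are therefore optimistic; the property tests assert calibration
only in the well-conditioned regime.

## Leave-one-out prediction

For each medication, the line is refitted on the other eight, warm-started
at the full-sample slope so every refit tracks the same branch the full fit
sits on. Removing either medication with an extreme craving effect size
(memantine or varenicline on heavy drinking) destroys the positive local
minimum entirely and those refits land on the steep negative branch — the
warm start makes this reproducible rather than initialization-dependent. One
abstinence refit (olanzapine removed) has no attracting fixed point near the
positive minimum and ends in a period-2 oscillation; it is reported at the
last iterate with `converged=False`, which lies within a few hundredths of
the stationary slope.

The predictive distribution propagates only the held-out medication's
craving-SE through the frozen refitted line: draws `x* ~ N(xᵢ, sxᵢ²)` mapped
to `a + b x*`. The predictive SD is therefore exactly `|b|·sxᵢ` (reported as
`predicted_se`); regression-coefficient uncertainty is deliberately not
propagated. Medications with several craving studies are represented by
their pooled craving estimate — the analysis unit everywhere else — rather
than a per-study mixture.

Coverage is scored by whether the observed pooled RCT effect lies inside the
central 95% interval of the draws. This point-in-interval rule is stricter
than a visual overlap of predictive and sampling distributions: on heavy
drinking it flags acamprosate (|obs − pred|/se ≈ 8.1) and baclofen (≈6.1) —
the two qualitative outliers — but also olanzapine (≈3.8) and marginally
varenicline (≈1.97). Treat the flag as a screening diagnostic, not a
hypothesis test.

## Synthetic data generator

The generator emulates the two-paradigm structure: true craving effects per
medication `~N(−0.2, 0.2²)`, true RCT effects on a generating line (default
slope 0.25, intercept −0.04, the scale of the real data), study-level truths
around them with between-study variances τ² (defaults 0.02 lab / 0.01 RCT),
and raw within-arm unit-variance normal outcomes summarized into arm
means/SDs. Default sample sizes mirror the literature: lab studies 15–25 per
arm (~40 total, matching the median lab study), trials 40–80 per arm (~120
total, matching the median RCT); 1–6 lab and 2–10 RCT studies per
medication; an outcome mix dominated by the heavy-drinking family.
Percent-days-abstinent studies are generated with the medication arm scoring
higher so the downstream sign flip recovers the intended negative effect.

What it does not emulate: dropout, skewed or zero-inflated drinking
distributions, publication-bias selection, within-trial correlation of
multiple outcomes, or crossover designs. Passing recovery tests demonstrate
the estimator chain is correct under its own assumptions, not that the real
literature satisfies them.

Under defaults mimicking the real data the craving measurement reliability
is ~0.5, and the errors-in-variables slope is so heavy-tailed that recovery
experiments are uninformative (coverage ~0.75 — an honest reflection of how
weakly these study conditions identify the slope).
`SyntheticConfig.moderate_noise()` provides the well-identified profile used
by the validation tests (craving spread 0.4, 4–8 lab studies of 40–80 per
arm: reliability ~0.95); there, across 200 simulations, bias is within Monte
Carlo error, 95% CI coverage ≈0.93–0.97 (raw SE), and type-I error ≈0.05.

## Numerical choices

* Profile-objective scan: 2001 slopes in θ = arctan b, bounded refinement to
  xatol 1e−13; fixed-point tolerance 1e−12, max 200 iterations.
* DL truncation at τ² = 0; degenerate DL denominator (≤0) returns τ² = 0.
* Both arm SDs zero → explicit error (undefined effect size); one zero SD is
  allowed (pooled SD still positive).
* Full double precision throughout; rounding only at display.
* The packaged tables transcribe the published 3-decimal values; recomputed
  slopes/SEs can differ from the published ones in the third decimal because
  the published fit used unrounded inputs.

## Known limitations

* Only 9 medications carry both endpoints; all inference is asymptotic on
  n = 9 points.
* Branch selection (above) means the headline slopes are conditional on the
  directional-hypothesis branch of a bimodal objective.
* Publication-bias correction is out of scope (it requires study-level
  effect sizes and a selection model ill-suited to random-effects pooling).
* The craving axis carries large measurement error; attenuation is handled
  by the errors-in-variables model, but calibration of the Wald test on
  these data is not nominal (see power section).
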