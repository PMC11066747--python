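# Methods

## Cosinor model and estimation

A stream of hourly observations `y_i` at times `t_i` (hours from the
reference midnight) is modeled as

    y_i = M + Σ_c A_c cos(2π (t_i − φ_c)/T_c) + e_i,   e_i ~ (0, σ²) iid,

with fixed periods `T_c` (default 8, 12, 24 h). Substituting
`β_c = A_c cos(2πφ_c/T_c)`, `γ_c = A_c sin(2πφ_c/T_c)` makes the model linear
in `(M, β_1, γ_1, …)`, estimated by ordinary least squares (numpy `lstsq`).
Back-transform: `A_c = √(β_c²+γ_c²)`, `φ_c = (T_c/2π)·atan2(γ_c, β_c) mod T_c`.

Conventions and numerical choices:

- **Acrophase** is reported in hours from the reference midnight to the
  component maximum, in `[0, T_c)` — not the negative-radians convention
  common in the cosinor literature (scaling between the two is linear,
  `rad = −2π·hours/T`). The reference is the midnight at the start of each
  modeling window, so acrophases are comparable across windows.
- **Standard errors.** Coefficient covariance is `σ̂²(XᵀX)⁻¹` with
  `σ̂² = RSS/(n−2C−1)`. Amplitude/acrophase SEs propagate the relevant
  covariance block through the polar transform to first order (delta
  method): `∇A = (β, γ)/A`, `∇φ = (T/2π)·(−γ, β)/A²`. For a numerically
  zero amplitude the acrophase is conventionally 0 and both component SEs
  are reported as missing (the transform has no derivative there). Delta SEs
  are accurate when the amplitude is large relative to its SE; the test
  suite checks them against Monte Carlo at moderate noise.
- **Percent rhythm / significance.** `PR_c` is the R² of a *refit*
  single-period model, not a partition of the full model's sums of squares,
  and `P_c` is the classical zero-amplitude F test of that refit, `F` with
  `(2, n−3)` df. `IPR`/`IP` are the R² and overall F test of the full model,
  `F` with `(2C, n−2C−1)` df. A constant series is defined to have `R² = 0`
  and `p = 1`; a numerically perfect fit has `p = 0`.
- **Magnitude / orthophase / bathyphase** come from evaluating the composite
  fitted curve on a 1-minute grid over one fundamental period (LCM of the
  periods, computed exactly for rational periods); ties break toward the
  earliest time. Closed forms exist only for single components, so the grid
  is used uniformly; the 1-minute resolution bounds the phase error at
  0.5 min, far below any downstream use.
- **Windows.** For each survey week `w` the fit uses hours of weeks
  `max(1, w−1)…min(n_weeks, w+1)`; edge weeks truncate to two-week windows.
  Equal observation weights, no autocorrelation correction.

## Preprocessing

Events are aggregated per clock hour into min/max/mean/sample-SD/count
streams (SD missing for single-event hours; empty hours missing in all
five). Missing runs are filled by linear interpolation between the nearest
observed anchors, `v_t = v_a + (t−a)(v_b−v_a)/(b−a)`; boundary runs with
only one anchor take the nearest observed value, which adds no trend.
`np.interp` implements exactly this rule. The discard rule is strict and
per-window: a window is retained iff its missing fraction is `< 0.20`.
Imputation never alters observed values and is idempotent.

## Productivity labeling

Daily 0–4 scores are averaged over all reported days of a survey week
(weekdays and weekends; any `n_days ≥ 1` counts, with `n_days` recorded for
sensitivity checks). A weekly mean `≥ 2` labels the week high-productivity
(boundary inclusive); a participant with `≥ 2` high weeks of the 3 survey
weeks is in the high-productivity group. Participants missing any survey
week's label are excluded from grouping — incomplete survey response is
expected in field studies.

## Correlation and aggregation

Step 1 pairs each rhythm parameter with the weekly mean score (the graded
score, not the binary label) across participants, per (feature, parameter,
week); pairs with a missing side are dropped cell-wise, and cells with
`n ≤ 28` complete pairs are excluded. Both sides are min-max normalized
across participants before the Pearson correlation — an affine map that
provably cannot change `r` or `p` (the suite asserts invariance to 1e-12);
it is retained for scale comparability of reported values. Significance is
the two-tailed t test, `t = r√((n−2)/(1−r²))` on `n−2` df. Acrophases enter
as linear variables on `[0, T)`; their circularity is deliberately not
modeled — a documented caveat, since a circular treatment would change the
estimand.

Steps 2–4 aggregate cells per sensor feature (across parameters) and per
rhythm parameter (across features), within each week and then overall:

- combined significance: Fisher's method, `X = −2Σ ln p_i` vs `χ²(2k)`;
  a single p-value passes through unchanged; `p = 0` inputs are clamped to
  the smallest positive float;
- combined correlation `C`: the mean of the cell coefficients individually
  significant at `α = 0.05`; undefined (blank) when none are;
- significance score `S = −log10(combined p)`, capped at 16 (roughly the
  double-precision resolution of a p-value near 1e-16);
- cross-week combination is hierarchical: Fisher over the three weekly
  combined p's, and the mean of the defined weekly C's. A flat variant that
  pools cell p-values across weeks is available (`method="flat"`).

The exact aggregation constants (significant-only averaging, the −log10
transform, the cap, α) are this package's definitions; all four are
configurable in `PipelineConfig`. Fisher's method assumes independent
tests, which correlated rhythm parameters violate; combined p-values are
therefore interpreted as ranking scores rather than literal error rates.

## Synthetic cohorts

The generator inverts the cosinor model. Per participant and feature a
profile (MESOR, per-period amplitude and acrophase, noise SD) is drawn
uniformly between group-specific low/high bounds; hour `t` of day `d` takes

    mesor + Σ_c a_c(d)·cos(2π(t − φ_c(d))/T_c) + ε_t,

where per *day* the acrophase is jittered `N(0, phase_jitter_sd²)` hours and
the amplitude scaled by `max(0, 1 + N(0, amp_jitter_sd²))`, with hourly
noise `ε_t`. Day-level (not hour-level) jitter is the deliberate choice: the
fitted SE parameters measure between-day inconsistency within a window, so
instability must live at the day scale to be visible to them.

Missingness is an alternating renewal process: geometric observed gaps
(mean `block_mean·(1−f)/f`) and geometric missing blocks (mean
`block_mean`, default 1.7 h), giving a long-run missing fraction `f`
(default 0.10). Daily productivity is
`clamp(round(2 + coupling·stability + N(0, σ_day)), 0, 4)` with
`σ_day = 0.7` and `coupling = 0.8`; `stability` is the cohort-standardized
negative phase-jitter SD. The round-and-clamp Gaussian latent yields a
near-normal score distribution centered at 2 with SD just under 1,
matching what evening-survey productivity instruments typically show. The
default cohort: 100 participants in two equal groups (phase jitter 0.5 vs
3 h/day), 3 features, 16 weeks, surveys in weeks 1, 6, 15.

Seeding is counter-based: one root seed expands to per-participant,
per-feature `SeedSequence(seed, spawn_key=(i, j))` substreams, so growing
the cohort never perturbs existing participants, and equal config + seed
reproduces every output bitwise.

**What the generator does not emulate:** raw sensor event logs (it generates
at the hourly-feature level), weekday/weekend structure, non-stationary
semester trends, non-Gaussian heavy-tailed noise, informative missingness
(missingness is independent of the signal), or cross-feature correlation
within a participant. Passing tests therefore demonstrate that the analysis
recovers effects *of the assumed generative form*; they do not certify
behavior on real sensor data with structured artifacts.

## Problem sizes and verification

The test suite verifies: exact recovery on noiseless streams (1e-6);
coefficient agreement with an independent normal-equations solve (1e-8, 50
random instances) and with statsmodels OLS; delta-method SEs within 5% of
100,000-draw Monte Carlo at three settings; zero-amplitude type-I error in
[0.04, 0.06] over 10,000 white-noise series of length 168; IPR ≥ max PR on
a 1,000-fit sweep; the Fisher combiner against the closed-form even-df
chi-square survival series (1e-10, 100 vectors) and scipy's combiner;
uniformity of the combined p under the null (KS band, 10,000 replicates);
the imputation formula on randomized anchors with the strict 20% boundary;
all 8 week-label combinations; normalization invariance; and end-to-end
planted-effect recovery — overall C negative for `PHI_SE-24` and positive
for `PR-24` in ≥ 18 of 20 cohort seeds at the default effect size. These
sizes keep the full suite under a minute on one CPU while leaving
Monte-Carlo margins comfortably wider than their tolerance bands.

## Known limitations

- Acrophase correlation ignores circular wrap-around (see above).
- Fisher combination over dependent cells inflates combined significance;
  S is a ranking score.
- The zero-amplitude F test assumes iid Gaussian errors; imputed hours and
  day-level jitter induce mild autocorrelation that the equal-weight OLS
  ignores (as does standard single-cosinor practice).
- Delta-method phase SEs are unreliable when the amplitude is within ~2 SEs
  of zero; such components are rarely significant anyway.
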