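# rhythmlink

Cosinor rhythmometry of hourly mobile-sensing feature streams and a
Fisher-combined correlation analysis linking rhythm parameters to
self-reported productivity.

The package is aimed at digital-phenotyping and chronobiology researchers who
have per-participant hourly behavioral features (activity counts, sleep
minutes, calories, phone usage, ...) over a multi-week study plus sparse
daily self-reports, and who want to ask: *do participants with more stable
biobehavioral rhythms report higher productivity?* Because raw smartphone and
wearable logs from such studies are typically private, the package includes a
first-class synthetic-cohort generator with planted, configurable
rhythm-stability effects, so every stage of the analysis can be validated by
parameter recovery.

## The model

Each participant × feature stream is fit by the multi-component cosinor
model,

```
y_i = M + Σ_c A_c · cos(2π (t_i − φ_c) / T_c) + e_i
```

with fixed candidate periods `T_c ∈ {8, 12, 24}` hours (nocturnal, diurnal,
circadian), estimated by ordinary least squares on the linearized
cosine/sine design. The fit reports, per component, the MESOR `M`
(rhythm-adjusted mean), amplitude `A_c`, acrophase `φ_c` (hours from
midnight to the component peak), their delta-method standard errors, the
percent rhythm `PR_c` (R² of the single-period model) and the zero-amplitude
F test `P_c`; for the full model the integrated percent rhythm `IPR`,
integrated P value `IP`, and the magnitude / orthophase / bathyphase of the
composite curve over the fundamental period (LCM of the periods, 24 h).

Models are fit in three-week windows centered on each survey week (week 6
uses weeks 5–7; edge weeks truncate). Streams are cleaned first: hourly
statistics, linear interpolation of missing runs, and discarding of any
window with ≥ 20% missing hours.

The correlation analysis then proceeds in steps: (1) per (feature, rhythm
parameter, week), the Pearson correlation between min-max-normalized
parameter values and weekly mean productivity scores, two-tailed t-test
p-value, keeping cells with more than 28 observations; (2) aggregation per
feature and per parameter within each week — the combined correlation `C` is
the mean of the individually significant (α = 0.05) coefficients and the
significance score `S = −log10` of the Fisher-combined p
(`X = −2 Σ ln p_i ~ χ²(2k)`), capped at 16; (3) hierarchical combination
across weeks; (4) ranked reports of the top features/parameters by |C| and
by S.

## Worked example

```python
import rhythmlink as rl

# a noiseless 24-h rhythm: 10 + 2·cos(2π(t−14)/24)
profile = rl.RhythmProfile(mesor=10, amp_by_period={24: 2}, acro_by_period={24: 14})
stream = rl.simulate_feature_stream(profile, n_hours=72, seed=0)
fit = rl.fit_cosinor(stream, periods=(24,))
print(fit.mesor, fit.amplitude[24.0], fit.acrophase[24.0], fit.percent_rhythm[24.0])
# 9.999999999999996 2.0000000000000004 14.0 1.0
```

The generating parameters are recovered exactly: MESOR 10, amplitude 2,
acrophase 14 h, percent rhythm 1 (the single 24-h component explains all
variance).

End to end, on a simulated 100-participant cohort in which half the cohort
has unstable rhythms (3 h/day acrophase jitter vs 0.5 h/day) and stability is
coupled to productivity:

```python
cfg = rl.PipelineConfig(seed=1).with_simulation(n_participants=100)
manifest = rl.run_pipeline(cfg, "run1")
```

writes `rhythms.csv` (one row per participant × feature × week, one column
per rhythm parameter), `cells.csv`, `scores.csv` and score matrices. In
`scores.csv` the overall aggregated correlation for `PHI_SE-24` (the
standard error of the 24-h acrophase — a rhythm *instability* measure) comes
out at −0.74, and for `PR-24` (goodness of the 24-h fit — a *stability*
measure) at +0.71: unstable rhythms go with lower reported productivity,
which is exactly the effect planted by the generator.

The same pipeline is exposed as a CLI:

```
rhythmlink run --out run1 --seed 1 --participants 100
rhythmlink simulate --out sim --seed 0
rhythmlink fit --in sim/streams.csv --weeks 1,6,15 --periods 8,12,24 --out rhythms.csv
```

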