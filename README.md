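# serialdep

Analysis toolkit for **serial dependence** in spatial delayed-response
(delayed-estimation) experiments: the attractive pull of today's response
toward the previous trial's stimulus, and its repulsive counterpart,
sensory adaptation.

In the task this package targets, an observer remembers the polar angle of
a briefly flashed target on an invisible circle and reproduces it after a
variable memory delay (or after a variable interval since the previous
trial). The response error `y` on each trial is modeled as a function of
`x`, the angular location of the *previous* trial's stimulus relative to
the current one. The package provides:

- **Preprocessing** (`serialdep.preprocess`) — near-origin response and
  3-SD error filters, circular LOESS removal of stimulus-location-dependent
  systematic error, subject exclusion by mean absolute error (> 10°), and
  trial-history annotation (`x_prev`, previous delay, and the `x_next`
  future-trial control predictor).
- **Tuning curves** (`serialdep.tuning`) — the derivative of Gaussian
  (DoG), `y = x·a·w·c·exp(−(wx)²)` with `c = √2·e½` so the amplitude `a`
  equals the peak height, and the Clifford adaptation function
  `sin(y+x) = sin x / √((s·cos x − c)² + sin²x)`, which can express
  "peripheral bumps" (bias reversal at large |x|). Fits minimize squared
  error; the effect size is the signed **peak-to-peak** of the fitted curve
  (positive = attraction). Also: circular moving-average curves and the
  sublinear variance-vs-delay power law `var ~ (delay + t)^β`.
- **Resampling inference** (`serialdep.resample`) — permutation tests that
  shuffle `x` against `y` and refit (one-sided by default; uniform p under
  the null), between-condition permutation comparisons, percentile
  bootstrap CIs, and Bonferroni correction. DoG refits use a profiled
  least-squares path that makes 10,000-resample runs take seconds.
- **Working-memory noise models** (`serialdep.wmmodels`) — maximum-
  likelihood fits, per delay condition, of three circular error models:
  EP (von Mises, concentration κ), VP (precision redrawn each trial,
  J ~ Gamma(J̄, τ), κ = Φ(J) with J = κ·I₁(κ)/I₀(κ)), and VMRW (population-
  coding von Mises random walk with spike count m ~ Poisson(ξ)); plus a
  DoG-shaped trial-history shift of the mean ("hybrid") and a swap mixture
  in which a fraction α of responses center on the previous stimulus.
  Models are compared by AICc averaged across subjects.
- **Synthetic sessions** (`serialdep.synthetic_data`) — a seeded generator
  with uniform stimulus angles, randomized delays {0, 1, 3, 6, 10} s,
  a delay-dependent DoG/Clifford history bias, smooth systematic error,
  and rare invalid responses, so the whole pipeline is testable against
  known ground truth.
- **Pipeline + CLI** (`serialdep.pipeline`, `serialdep` console script) —
  simulate/load → preprocess → per-condition tuning fits → permutation and
  bootstrap statistics → variance power law → noise-model comparison, with
  deterministic seeded JSON reports.

## Worked example

```python
import numpy as np
from serialdep import pipeline, synthetic_data as syn

gen = syn.GeneratorConfig(
    n_subjects=12, n_trials_per_subject=1000,
    systematic_error=[(1, 1.5, 20.0), (4, 0.8, 0.0)],
    outlier_rate=0.005, origin_click_rate=0.01, seed=0,
)
cfg = pipeline.AnalysisConfig(generator=gen, grouping="current_delay",
                              n_perm=800, n_boot=800, seed=0)
rep = pipeline.run_analysis(cfg)
for d, c in rep["conditions"].items():
    print(d, round(c["fit"]["peak_to_peak"], 2), c["permutation"]["p_value"])
```

prints (peak-to-peak in degrees, permutation p):

```
0 -1.24 0.13375
1 0.93 0.2575
3 1.76 0.14375
6 3.06 0.06375
10 2.38 0.115
```

The generator's default amplitude schedule injects weak adaptation at the
0-s delay and attraction that peaks at 6 s; the recovered time course
shows exactly that sign flip and peak (injected peak-to-peaks were
{−1.72, 0.84, 2.0, 3.4, 2.9}°). With a 12-subject cohort split across
five delays the per-condition permutation p-values stay modest — the
effect sizes, not the p-values, are the calibrated quantities at this
sample size.

The same analysis from the shell:

```bash
serialdep simulate --n-subjects 2 --n-trials 1000 --seed 0 --out trials.csv
serialdep preprocess trials.csv --out prep/
serialdep fit-tuning prep/annotated_trials.csv --model dog
serialdep permtest prep/annotated_trials.csv --n-perm 10000 --seed 1
serialdep run --config analysis.json --seed 1 --out out/
```

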