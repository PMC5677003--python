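# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, and what the synthetic-data generator does
and does not emulate.

## Conventions

Public angles are degrees of polar angle. Absolute angles live on
[0, 360); signed differences and errors on (−180, 180], wrapped by
`wrap_signed`. Positive error means counterclockwise; `x_prev` is the
previous stimulus angle minus the current one, wrapped, so *attraction*
means the error shares the sign of `x_prev`. Likelihood computations
convert errors to radians at the module boundary; all concentration and
precision parameters (κ, J̄, τ) are therefore radian-scale.

## Trial-history tuning curves

**DoG.** `y = x·a·w·c·exp(−(wx)²)` with the fixed constant
`c = √2/e^(−1/2)`, chosen so that the curve's extrema at `x = ±1/(w√2)`
have height `±a`. The signed peak-to-peak of a DoG is exactly `2a`
whenever the peaks fall inside ±180°. The width is bounded to
`w ∈ [1e-4, 0.2]` per degree: the upper bound stops the optimizer from
collapsing the curve into a spike supported by a handful of trials, the
lower bound keeps the curve non-degenerate.

**Clifford.** The implicit adaptation model
`sin(y + x) = sin x / √((s·cos x − c)² + sin²x)` has two arcsine branches;
the package resolves the ambiguity with the vector-angle construction
`y = atan2(sin x, s·cos x − c) − x` (wrapped), which is continuous and
passes through `y(0) = 0`, and satisfies the implicit equation to
round-off. A `sign` of −1 mirrors the curve (the raw form models
adaptation; serial dependence is its negative). Parameter pairs for which
the defining vector vanishes at some angle are rejected as degenerate.

**Fitting.** The DoG is linear in `a` for fixed `w`, so fitting profiles
the width: `â(w) = Σg·y / Σg²` with `g = dog(x; 1, w)` on a 40-point
log-spaced width grid, two local zoom rounds, then a bounded
Levenberg–Marquardt polish of both parameters. This is the exact
least-squares optimum (verified against dense width grids) and, crucially,
vectorizes across thousands of permutation or bootstrap refits. The
Clifford fit is multi-start trust-region least squares over (s, c) for
both orientations, from s ∈ {0.8, 1, 1.2} × c ∈ {−0.3, 0, 0.3}.

**Peak-to-peak.** Curves are evaluated on a 0.05° grid over [−180, 180];
each grid extremum is polished by bounded scalar optimization, so the
analytic identity `p2p(DoG(a, w)) = 2a` holds to better than 1e-6. The
sign is that of the first local extremum at positive `x` (the
"small-positive-x peak"); a curve monotone to the boundary takes the sign
of its value at 180°. Positive = attraction.

**Model choice.** The DoG is the default. The `auto` policy fits both
curves and switches to Clifford only when its AICc (from the SSE under
Gaussian-error equivalence; both models have two parameters) is lower by
more than 2 — an explicit, reproducible version of the qualitative
"poor fit" judgment; ties keep the DoG.

## Resampling inference

Permutation tests shuffle `x` while leaving `y` in place and refit. The
default p-value is the proportion of null peak-to-peaks greater than or
equal to the observed one: a one-sided test of attraction whose p is
uniform under the null (verified by simulation; measured type-I 0.05–0.06
at α = 0.05). `alternative="less"` tests repulsion;
`alternative="auto"` picks the tail from the observed sign, which is what
the pipeline's descriptive condition tables use (an adaptation-shaped
condition is then tested in the repulsive direction) — but because the
direction is chosen post hoc, `auto` doubles the type-I rate and should
not be used for confirmatory single-direction tests. p = 0 is stored as
the raw proportion and printed as `< 1/n_perm`.

Condition comparisons shuffle within each condition independently and
compare the observed difference of peak-to-peaks to the null differences.
Bootstrap CIs are percentile intervals from joint (x, y) pairs resampling.
Default resample counts are 10,000; the test suite and acceptance script
use 500–2,000.

## Working-memory noise models

- **EP**: a single zero-mean von Mises with concentration κ (one
  parameter). Computed as `exp(κ(cos e − 1)) / (2π·I₀(κ)·e^(−κ))` via the
  exponentially scaled Bessel function, stable to κ ~ 10⁵.
- **VP**: Fisher information `J ~ Gamma(mean J̄, scale τ)` per trial,
  κ = Φ(J) inverting `J(κ) = κ·I₁(κ)/I₀(κ)`. The scalar inverse uses
  bracketed root finding (round-trip < 1e-8); the vectorized path uses
  monotone log-log interpolation on a 6000-point grid. The marginal
  density is the Monte-Carlo average of von Mises components over J draws.
- **VMRW**: the report is the direction of the resultant of m unit
  vectors with i.i.d. von Mises(0, κ) directions, m ~ Poisson(ξ).
  Conditional on resultant length r the error is VM(0, κr), and r follows
  the Bessel-tilted walk-length density
  `p(r|m, κ) = I₀(κr)/I₀(κ)^m · rψₘ(r)`. Sampling the step *directions*
  from VM(0, κ) draws r from exactly that tilted law, so the density is
  the unweighted Monte-Carlo average of VM(κr) components (m = 0
  contributes 1/2π). The forward-simulation cross-check in the tests uses
  the independent decoding route — the *angle* of the resultant — and the
  two routes agree to total-variation distance < 0.01 at (κ = 2, ξ = 10)
  with 2×10⁵ draws.

**Monte-Carlo determinism.** Each optimizer run fixes one set of uniform
draws: Poisson counts come from PPF inversion on stratified uniforms, von
Mises steps from quantile-grid inversion (2049-point CDF grid), and VP's
gamma draws from `gamma.ppf`. The simplex objective is therefore
deterministic and varies near-smoothly with the parameters; naive
re-sampling per evaluation makes simplex search unstable. Densities for
likelihoods are evaluated on a 721-point error grid (0.5° spacing) with
linear interpolation.

**History extensions.** `dog_shift` moves the density's mean by
`DoG(x_prev; a, w)` on each trial (two extra parameters); `swap` mixes the
base density with the same density centered on the previous trial's
stimulus, with mixing weight α (one extra parameter). Trials without a
previous trial use the base density.

**Fitting and comparison.** Nelder–Mead on log-transformed positive
parameters (α logit-transformed), two starts per base model plus two per
extension, independently per delay condition; κ starting values come from
the resultant-length moment estimate. AICc = 2k − 2LL + 2k(k+1)/(n−k−1)
with k counting all per-condition parameters. ΔAICc is reported per
subject and summarized as mean ± SEM; positive values favor the
first-named model. A per-subject VMRW caveat: at n ≈ 1000 the (κ, ξ)
likelihood has a ridge — the identifiable combination is the effective
concentration κ·(I₁/I₀)(κ)·ξ — so individual VMRW parameters should not
be over-interpreted even though model comparison by AICc is well behaved.
No uniform-lapse component is included: in a single-item spatial task
guess rates are near zero, and the VMRW's m = 0 term already supplies a
uniform ingredient.

## Preprocessing

Raw error = response − stimulus, wrapped. History annotation runs
*before* trial filtering: a trial dropped for an invalid response still
donates its stimulus as the previous-trial predictor of the next trial.
Filters: responses within 5° of visual angle of the origin, then — per
subject, in one pass, using the signed-error mean and SD of the survivors
— errors further than 3 SD from the subject's mean. Systematic error is
estimated per subject by LOESS (tricube, locally linear, default span
0.3) on the data concatenated at ±360° shifts and evaluated on the
central copy, giving a strictly periodic estimate; the estimate is
recentered so its circular-grid mean equals the subject's mean error, and
is subtracted from each trial. Subjects with mean absolute error strictly
greater than 10° (or fewer than 10 surviving trials) are excluded from
group analyses.

## Variance time course

Per-delay response variance with percentile-bootstrap CIs, then least
squares of `scale·(delay + t)^β` (t log-parameterized, hence positive,
multi-start over t and β) against a straight-line fit; both SSEs are
reported so the sublinearity claim is a model comparison, not an
assertion.

## Synthetic-data generator

Each subject's stream is seeded by (seed, subject index), so subjects are
independently reproducible and sessions are fully deterministic. Per
trial: stimulus ~ Uniform[0, 360); delay and ITI from weighted sets
(defaults: delays {0, 1, 3, 6, 10} s uniform, fixed 1-s ITI); error =
systematic error (low-order sinusoids, default off) + history bias
(DoG/Clifford with a delay-dependent amplitude; none on a subject's first
trial) + circular noise from EP, VP, or VMRW, wrapped. Default noise is
EP with κ(d) set from the sublinear variance law
`var(d) = 15.75·(d + 2.67)^0.47` deg², and the default amplitude schedule
is {−0.86, +0.42, +1.0, +1.7, +1.45}° for delays {0, 1, 3, 6, 10} s —
adaptation at the shortest delay flipping to attraction that peaks at
6 s, at half the peak-to-peak scale. Invalid trials: with probability
`origin_click_rate` the response eccentricity is drawn below the 5°
filter threshold (valid responses sit at the 12° stimulus ring); with
probability `outlier_rate` the error is replaced by a uniform draw beyond
3 SD of the session noise, a deliberately crude stand-in since real
outlier shapes are unknown.

What the generator does *not* emulate: reaction times, eye movements,
learning or fatigue trends, subject-specific tuning shapes (peripheral
bumps arise only if a Clifford bias is configured), and any
delay-dependence of the *noise family* (only the parameters vary by
delay). Passing recovery tests therefore shows the estimators are
calibrated for data with this statistical structure, not that real data
satisfy it.

## Problem sizes in the tests and acceptance script

The test suite calibrates the permutation test and bootstrap on 200
synthetic sessions of 500 trials (1000 permutations / 500 bootstrap
resamples each), runs the model-recovery confusion on 20 seeds × 1000
trials, the amplitude-recovery ensemble on 400 seeds, and the end-to-end
cohort at 12 subjects × 1000 trials with 800 resamples. The acceptance
script uses the same cohort size with 1000 resamples and fits the noise
models at group level with a separate parameter set per delay. These
sizes were chosen so
the whole suite runs on a single CPU in well under half an hour while
keeping Monte-Carlo error small relative to every tolerance tested.
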