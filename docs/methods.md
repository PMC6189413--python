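# Methods

This note documents the models, conventions, and numerical choices behind
`jointcoord`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and data model

A *session* is one agent's view of 384 trials (4 blocks × 96): every trial
carries the stimulus (side, color), which agent's response it required, and —
on the agent's own go trials — their response, RT (ms), and accuracy
(`correct` / `error` / `miss`).  In a joint session the two agents share one
stimulus schedule and each responds to one color (192 go trials each); in an
individual session an agent works through their own schedule alone, the
other color acting as no-go.  Trial logs are CSV
(`pair_id, agent_id, condition, design, block, trial_index, stimulus_side,
stimulus_color, required_responder, response_side, rt_ms, accuracy`), with
missing RT as an empty field.

**Correspondence** of a trial is C when the stimulus side equals the
*required* responder's key side, NC otherwise.  Coding from the required
mapping (rather than the executed response) defines correspondence on no-go
and error trials too, which the sequential analysis needs for its
previous-trial factor.  Key sides are inferred from each agent's recorded
responses (modal side; the co-agent sits at the opposite key).
**Transition** classifies trial *n* from one agent's perspective: Go/go if
trial *n−1* required that agent's response, Nogo/go otherwise; undefined on
the first trial of each block.

### Filters

- *Mean/distributional analyses*: correct go-trial responses only.
- *Sequential analysis*: additionally discards first-of-block trials and
  trials whose immediately preceding trial ended in an error or miss — by
  **either** member in joint sessions, since the pair shares one trial
  stream.  (An error at *n* removes both *n* and *n+1*.)
- *Participant exclusion*: Tukey fences (Q1 − k·IQR, Q3 + k·IQR, k = 1.5,
  quartiles by linear interpolation) on per-participant error counts,
  per condition by default; a pair is excluded when either member is flagged
  in either condition.  Misses count as errors throughout.

## Effect tables

All tables use two-stage averaging — cell means per participant, then an
unweighted mean (and SD) across participants — which matches the
participant-as-unit logic of the ANOVAs.  The quartile analysis sorts each
participant × condition × correspondence cell ascending and splits it into
four equal-count bins, any remainder going to the earliest bins; the
bin-size-weighted mean of bin means reproduces the cell mean exactly.
Binning within correspondence is the default (a pooled variant is
available).  The transition table crosses transition × previous × current
correspondence and reports `SE = NC − C` per row.  Values are kept at full
precision; `round_half_away` provides the integer-ms table formatting.

## Instantaneous cross-correlation

RT series: the agent's go trials in collection order; error/missing RTs are
substituted with the mean of that participant's correct RTs in that
condition, and the same mean then centers the series (imputed points sit at
zero, the series mean is exactly zero).

The smoother is the zero-phase first-order exponential filter: forward pass
`y[t] = η·x[t] + (1−η)·y[t−1]` initialized at `y[0] = x[0]` (this preserves
constants exactly), then the identical recursion backward over the forward
output.  Its interior impulse response is the normalized two-sided
exponential `w[d] ∝ (1−η)^|d|`, an effective window of ≈ 2/η − 1 ≈ 19 trials
at the default η = 0.1; `η = 1` is the identity.  The test suite pins these
semantics two ways: an exact finite-sample kernel-matrix oracle (closed-form
geometric weights) and the asymptotic kernel on interior points.

For each lag δ ∈ [−9, +9], the lagged pair (x[t], y[t+δ]) is formed over the
overlapping index range; the five local moment series ⟨x⟩, ⟨y⟩, ⟨x²⟩, ⟨y²⟩,
⟨xy⟩ are smoothed and combined into a local Pearson coefficient.  Filtering
moments (not r itself) keeps r a genuine correlation, bounded by
construction; it is additionally clipped to [−1, 1] against floating-point
overshoot.  Cells with local variance below 1e−12 or an out-of-range partner
index are invalid — no zero padding.  The **coordination index** is the
fraction of valid cells with signed r > 0.25 (an absolute-value variant is a
flag).  Pseudo-pairs align the two members' individual-session series by
ordinal go-trial index, the only alignment that gives equal-length series in
both conditions; length mismatches beyond 10% warn before truncation.

## Inference

*Paired t*: classical; Cohen's d = mean difference / SD of differences;
Bonferroni correction `min(1, p·m)`.  Zero-variance differences are reported
as t = 0 (all equal) or ±∞ with p = 0.

*Repeated-measures ANOVA*: for fully crossed within designs with one
observation per participant per cell, each within effect (every nonempty
factor subset) is tested against its effect-by-participant stratum; with a
between factor, split-plot error terms are used (effects by
participants-within-groups) and group means are weighted by group size when
groups are unequal.  Effect size is partial η² = SS_effect/(SS_effect +
SS_error).  The decomposition is verified in tests against an independent
projection-matrix computation and against `statsmodels` AnovaRM for the
pure-within case.  Sphericity corrections are not applied (all factors of
interest have two levels; the four-level Bin factor is analyzed uncorrected,
matching standard practice of reporting uncorrected df for it).

*Mixed-model comparison*: Model 1 fits per-participant cell means with fixed
effects Condition × Correspondence and a random intercept per participant;
Model 2 adds a pair-level random effect whose loading is the pair's
coordination index (a random slope on the covariate — one extra variance
parameter, df 5 → 6).  Both use maximum likelihood, not REML, because the
models differ in random structure; the statistic 2·ΔlogLik is referred to
χ²(1).  Implementation uses `statsmodels` MixedLM with pairs as groups and
participant intercepts as a variance component (MixedLM has a single
grouping level).  Testing a variance component on its boundary makes the
1-df χ² conservative — the result object flags boundary estimates, and the
plain χ² is reported as primary.  Note the statistic is a boundary mixture
(~½·0 + ½·χ²(1)) under the null: its *median* over replicates is ~0 even
though single draws can be large.  Non-convergence is reported, never
silently replaced.

## Synthetic dyads

Per go trial of agent *a*:

```
RT = μ + (β/2)·s + seq + z_a + ε,   ε ~ N(0, σ_rt²)
```

with `s = +1` (NC) / `−1` (C), so NC − C recovers β while the grand mean
stays at μ.  Sequential modulation `seq = +(λ/2)·s` after a corresponding
trial and `−(λ_rev/2)·s` after a non-corresponding one, gated by default to
Nogo/go transitions; the row effects of the transition table are then
`β + λ` (post-C) and `β − λ_rev` (post-NC).  The latent fluctuation
`z_a = √c·u + √(1−c)·v_a` mixes a shared and a private stationary AR(1)
process (coefficient φ, SD σ_latent), indexed over the full 384-trial
schedule and sampled by each agent on their own go trials — so coupling `c`
survives the go-trial subsetting the coordination analysis performs.
Correspondence is balanced exactly (fixed multiset per block per responder,
shuffled), eliminating binomial noise from schedule composition.  Errors and
misses are one pooled process (probability `p_error` per go trial, split
evenly), recorded separately in the ground truth.  RTs clip at `rt_floor`.
Batch runs derive one child RNG stream per pair (then per condition) from
the root seed via `SeedSequence.spawn`.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| blocks × trials | 4 × 96 | standard session length for this task |
| μ | 325 ms | mid range of typical go/no-go Simon means |
| σ_rt | 32 ms | with σ_latent gives total correct-RT SD ≈ 36.7 ms, inside the typical 30–45 ms band |
| β | 10 ms | joint-condition effect under cooperation; presets use 2 ms (individual, cooperative), 5/4 ms (competitive) |
| λ, λ_rev | 14, 19 ms | reproduce the ~24 ms / −9 ms Nogo/go row effects at β = 10 |
| φ, σ_latent | 0.9, 18 ms | see below |
| p_error | 0.005 | error rates of ~0.4–1.1% |
| rt_floor | 150 ms | physiological lower bound |
| coupling | 0 (preset: 0.8 joint-cooperative) | competitive joint sessions couple at 0 and run ~34 ms faster |

φ and σ_latent are not identified by published summary statistics; they were
chosen so that the latent process behaves like the slow, large RT drifts real
observers show *and* so that coupling measurably transmits into the analyzed
series: each agent samples the shared process only on their own go trials,
so a fast-decaying or small latent component would leave nothing for the
cross-correlation to detect.  At φ = 0.9, σ_latent = 18 the cooperative
preset yields ≈ 11.8% joint vs ≈ 7.8% pseudo-pair coordinated activity — the
qualitative cooperative/competitive asymmetry this pipeline is built to
measure.

### What the generator does and does not emulate

It emulates the session structure, exact correspondence balance, go/no-go
splitting, realistic RT level/variability, a switchable Simon effect with
Nogo/go-gated sequential modulation, pooled errors/misses, and latent
coupling.  It does **not** emulate: RT skew (Gaussian noise, no ex-Gaussian
tail), practice/fatigue trends, speed–accuracy trade-offs (errors are
independent of RT), handedness or seating counterbalance, or feedback-driven
motivation.  Passing tests therefore show the *pipeline* recovers what was
injected under controlled conditions — not that real data satisfy these
assumptions.

## Numerical and policy choices

- Quantile convention everywhere (Tukey fences, quartile bins): linear
  interpolation between order statistics / equal-count splits with extras to
  the earliest bins.
- Coordination matrix rows index time in the first series; the swap symmetry
  r_xy(t, δ) = r_yx(t+δ, −δ) holds to 1e−10.
- Series of unequal length truncate to the shorter with a warning.
- The lag range is fixed at ±9 by default; it scales as a config option
  rather than by any automatic rule.
- JSON summaries round floats to 10 decimals and sort keys, making reruns
  byte-identical under a fixed seed.

## Problem sizes

Monte-Carlo checks in the tests and acceptance script use 200 pairs for
parameter recovery, 100 seed replicates for the coordination discrimination
and mixed-model power, 20 suites × 10 pairs for the null-coupling contrast,
and 1000 replicates × 10 pairs for type-I calibration — sizes at which the
binomial/standard errors of the checked rates are well inside the asserted
bands.

## Known limitations

- The within-subject ANOVA assumes one observation per cell (aggregate
  first) and complete designs; unequal between-groups use weighted group
  means (classical sums of squares), which conflates effects with group-size
  imbalance in strongly unbalanced designs.
- MixedLM variance components can sit on the boundary; the reported χ² is
  then conservative.
- The coordination index depends on η, the lag range, and the threshold
  jointly; comparisons are only meaningful at fixed settings (defaults:
  η = 0.1, lags ±9, r > 0.25).
- Imputing error/miss RTs at the condition mean slightly deflates local
  variance around imputed points; with error rates ~1% the effect is
  negligible, but the imputation mask is retained for sensitivity checks.
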