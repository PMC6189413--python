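# jointcoord

Analysis pipeline for **dyadic go/no-go Simon experiments**: estimation of the
joint Simon effect (mean, distributional, and sequential decompositions) and
of **inter-agent response coordination** via instantaneous cross-correlation
of reaction-time series, plus a synthetic dyad generator that gives every
stage a known ground truth.

## The problem

In a go/no-go Simon task two people share a two-choice task: each responds to
one stimulus color with their own key while stimulus *location* is irrelevant.
Performed alone, the spatial correspondence between stimulus and key barely
matters; performed side by side, responses become faster on corresponding
trials — the **joint Simon effect (JSE)**, `JSE = mean(RT_NC) − mean(RT_C)`,
read as an index of shared task representations.  A complementary question is
whether co-agents' trial-by-trial response times **co-fluctuate**.  This
package implements both analyses for trial-level RT logs:

- **Effect tables** — condition × correspondence means (two-stage,
  participant-then-group averaging), rank-ordered quartile-bin means
  (Vincentizing), and the 2×2×2 transition table of sequential
  (conflict-adaptation) effects, with rowwise `SE = NC − C`.
- **Coordination** — each agent's go-trial RT series (collection order,
  error/missing RTs imputed with the participant-condition mean, then
  centered) is compared with the partner's at trial lags −9…+9.  Local
  first/second moments are smoothed with a zero-phase first-order
  exponential filter (η = 0.1, forward then backward recursion) and combined
  into a local Pearson coefficient r(t, lag); the **coordination index** is
  the proportion of valid (t, lag) cells with r > 0.25.  Pseudo-pairs (the
  same two people during their parallel individual sessions) provide the
  no-interaction baseline.
- **Inference** — paired t tests with Bonferroni correction and Cohen's d,
  repeated-measures factorial ANOVA (up to four within factors plus one
  between factor, partial η²), and an lme4-style mixed-model comparison
  testing a pair-level random effect of coordination with a 1-df χ²
  likelihood-ratio test (ML fits).
- **Simulation** — pairs of sessions (384 trials, 4 blocks of 96, exact
  correspondence balance) with a tunable Simon effect β, Nogo/go-gated
  sequential modulation λ, error/miss process, and inter-agent coupling `c`
  carried by a shared slow AR(1) latent process:
  `RT = μ + (β/2)·s + seq + z_a + ε`, `z_a = √c·u + √(1−c)·v_a`.

## Worked example

```python
from jointcoord import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(sim=SimConfig(seed=1), n_pairs=10, design="cooperative")
summary = run_pipeline(cfg, "simulate", out_dir="results/demo")
print(summary["simon_effect_ms"])
print(summary["coordination_pct"])
print(summary["paired_t_coordination"])
```

prints (one pair is excluded by the Tukey error-count fences, leaving 9):

```
{'individual': 1.655091911, 'joint': 8.6995071322}
{'individual': 6.9483480107, 'joint': 12.6069577166}
{'statistic': 4.3316693738, 'df': 8, 'p': 0.0025063394,
 'p_corrected': 0.0025063394, 'effect_size': 1.4438897913}
```

The cooperative preset injects a 10 ms joint (2 ms individual) Simon effect
and coupling 0.8: the recovered JSE is ~9 ms in the joint condition and ~2 ms
alone, and joint pairs show ~12.6% coordinated activity against ~6.9% for
pseudo-pairs — a reliable paired contrast (t(8) = 4.33, p = 0.0025, d = 1.44).
The same summary also contains the quartile-bin means, the sequential
transition table (large positive Nogo/go effect after corresponding trials,
reversed after non-corresponding ones), the ANOVA table, and the mixed-model
comparison.  Note the χ² here is ~0: the generator does not make cell means
depend on a pair's coordination level, so the coordination random effect has
nothing to explain — it becomes significant exactly when that dependence is
real (see `tests/test_inference.py`).

The same workflow is available from a shell:

```bash
jointcoord simulate --seed 1 --pairs 10 --out runs/sim
jointcoord analyze --input runs/sim/trials.csv --out runs/results
jointcoord report --in runs/results
```

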