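# foreprep

Analysis pipeline for **variable-foreperiod (temporal preparation) experiments**:
behavioral studies in which a warning stimulus (S1) precedes a target (S2) by a
variable foreperiod (FP), and reaction times (RTs) to the target reveal how well
participants anticipated *when* it would appear. The package targets two-phase
designs in which each of two S1 categories is implicitly paired with a biased FP
distribution (exponential vs. anti-exponential) during an *Acquisition* phase and
with a uniform distribution during a *Transfer* phase, probing whether the learned
category–timing association persists.

It is written for experimental psychologists and cognitive neuroscientists who want
a tested, scriptable version of this analysis stack, end-to-end runnable on
synthetic data.

## What it computes

- **Synthetic data** (`foreprep.design`, `foreprep.simulate`): exact balanced trial
  sequences (per-block FP×S1-type×side counts are deterministic, order is
  randomized) and a generative inverse-RT model
  `1/RT = (β₀ + u₀ᵢ + fatigue(t)) + (β_FP + u₁ᵢ)·FP + β_S1·S1 + β_int(t)·FP·S1 + ε`
  with a gradually *learned* S1×FP interaction, a transient suppression ("dip") at
  the Transfer boundary, correlated subject-level random effects, response errors
  and RT outliers.
- **Preprocessing** (`foreprep.preprocess`): participant screening (mean correct RT
  beyond 2.5 sample SDs; accuracy below 95%), removal of incorrect trials and of
  trials whose log RT lies more than 3 SDs from the participant mean, and the
  analysis response `1/RT`.
- **Mixed-model comparison** (`foreprep.lmm`): maximum-likelihood linear mixed
  models of 1/RT with FP as a continuous predictor and a correlated random
  intercept + FP slope per participant; evidence via the BIC approximation to the
  Bayes factor, `BF ≈ exp(ΔBIC/2)`.
- **Rolling regression** (`foreprep.rolling`): per-participant sliding-window OLS
  (default 60 trials) of 1/RT on Intercept, FP, S1 type and FP×S1, baselined to
  Δβ = β(t) − β(first window).
- **Cluster-based permutation inference** (`foreprep.clusters`): one-sample
  cluster-mass t-tests on Δβ time courses with a participant sign-flip null,
  max-statistic correction, and exhaustive enumeration for n ≤ 12.
- **Power simulation** (`foreprep.power`): scale down the S1-type effects, simulate
  Transfer-phase datasets over a sample-size × effect-scale grid, and estimate
  power from likelihood-ratio tests.
- **Descriptives** (`foreprep.report`): RT–FP curves with 95% Cousineau–Morey
  within-subject CIs and annotated Δβ time-course figures.

## Worked example

```python
from foreprep import *
from foreprep.lmm import ModelSpec

trials = simulate_experiment(DesignSpec(), GenerativeParams(),
                             n_participants=49, seed=11)
clean, screen, filt = preprocess(trials)

full    = fit_model(clean, ModelSpec("fp_by_s1type", ("FP", "S1type", "FP:S1type")))
reduced = fit_model(clean, ModelSpec("fp_only", ("FP",)))
comp = compare_models(full, reduced)
print(f"delta BIC = {comp.delta_bic:.2f}; {comp.bayes_factor}")

tc = rolling_timecourse(clean, window=60)
group = align_timecourses(tc, "FPxS1type")
for c in permutation_test(group, n_perm=2000, seed=5):
    if c.significant:
        print(f"{c.sign} cluster, trials {c.start_center}-{c.end_center}, "
              f"mass {c.mass:.1f}, p = {c.p_value:.4f}")
```

Output:

```
delta BIC = 627.17; BF > 1000
positive cluster, trials 317-417, mass 256.2, p = 0.0255
positive cluster, trials 462-694, mass 759.3, p = 0.0010
positive cluster, trials 771-843, mass 242.4, p = 0.0280
```

Two participants were screened out (47 retained; on average 0.67% of correct
trials discarded as log-RT outliers). The BIC comparison overwhelmingly favors
including the S1-type terms: the simulated categories produced differential
preparation. The cluster test recovers the injected learning dynamics: the
FP×S1 interaction Δβ rises into significant clusters during mid/late Acquisition
(trials ~317–694, i.e. Blocks 3–6), vanishes at the Transfer boundary (the
post-questionnaire dip), and returns in a significant Transfer-phase cluster
(trials 771–843).

The same pipeline is available from the shell:

```bash
foreprep simulate --n-participants 49 --seed 11 --out trials.csv
foreprep preprocess --in trials.csv --out clean.csv --report filter.json
foreprep timecourse --in clean.csv --window 60 --out tc.csv
foreprep clusters --in tc.csv --coef FPxS1type --n-perm 10000 --seed 5 --out clusters.json
foreprep report --trials trials.csv --timecourses tc.csv --clusters clusters.json --outdir figs/
```

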