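# Methods

This note documents the statistical procedures implemented in `foreprep`, the
assumptions behind the synthetic-data generator, and the numerical and design
choices made where conventions differ across labs.

## The analysis problem

In a variable-foreperiod task, the interval (FP) between a warning stimulus (S1)
and a target (S2) varies across trials. Mean RT as a function of FP — the RT–FP
curve — indexes temporal preparation: a flat curve means the participant is ready
at all FPs, a steep downward slope means preparation builds only as time elapses.
When two S1 categories are paired with different FP distributions (exponential:
mostly short FPs; anti-exponential: mostly long), differential preparation
appears as a *category × FP interaction* on RT. The pipeline quantifies (i)
whether that interaction is present (mixed-model comparison), (ii) how it
develops trial by trial (rolling regression + cluster inference), and (iii) what
sample sizes detect it (power simulation).

All models are fit on inverse RT, `y = 1000 / RT_ms` (unit 1/s), which largely
removes the right skew of RT distributions and makes a homoscedastic Gaussian
residual a reasonable approximation.

### Predictor coding

One fixed coding is shared by the generator, the mixed models and the rolling
regression (`foreprep.coding`): FP in seconds centered at the 750 ms design
midpoint; S1 type effect-coded −0.5 (exponential, E) / +0.5 (anti-exponential,
A); phase effect-coded −0.5 (Acquisition) / +0.5 (Transfer). Main effects are
therefore evaluated at the average of the other factors, coefficients are O(1),
and rolling-window coefficients are comparable across windows because the
centering constant is never re-estimated. The centering constant is fixed at the
design midpoint rather than a per-dataset mean so that coefficients keep the same
meaning across designs and windows.

## Synthetic-data generator

### Design generation

Trial sequences are generated exactly, not stochastically: per Acquisition block,
32/16/8/4 trials per FP (300/600/900/1200 ms) for the exponential S1 type and the
reverse for the anti-exponential type; 15 per FP per type in Transfer blocks
(120-trial blocks; defaults 6 Acquisition + 2 Transfer, 960 trials). S2 side is
exactly balanced within S1 type within block; the FP–side pairing and the trial
order are the only random elements (jointly shuffled after the balanced multiset
is built, since the balancing constraints do not tie a particular side to a
particular FP). The category→type assignment alternates with participant parity
(odd: first category is exponential), implementing full counterbalancing. Each S1
is a unique integer image id; the inter-trial interval is sampled uniformly from
750–1500 ms and carried as metadata only.

### Generative RT model

Inverse RT of trial *t* for participant *i*:

```
y_it = (β₀ + u₀ᵢ + fatigue(t)) + (β_FP + u₁ᵢ)·FP_c + β_S1·S1_c + β_int(t)·FP_c·S1_c + ε_it
```

- `(u₀ᵢ, u₁ᵢ)` — bivariate Gaussian random intercept and FP slope
  (SDs 0.25 and 0.08 1/s, correlation −0.3);
- `ε_it ~ N(0, 0.30²)` on the inverse-RT scale (equivalent to roughly a 50 ms
  residual SD at a 400 ms RT);
- `fatigue(t)` — linear intercept drift from 0 to −0.12 1/s across each block,
  resetting at every block break (participants slow within a block, recover at
  breaks);
- `β_int(t)` — the *learned* interaction: a saturating ramp
  `β_int_max · (1 − 2^(−t/λ))` over Acquisition trials with half-life λ = 150
  trials, held at its end-of-Acquisition value during Transfer except for a
  multiplicative suppression at the first Transfer trial (depth 1.0, i.e. full)
  that recovers linearly over 60 trials. The dip emulates the transient effect of
  being told, between phases, that the category–FP contingency no longer holds.
  In a Transfer-only design the interaction sits at its asymptote with no dip
  (there is no intervention to dip from). Setting `β_int_max = 0` (and `β_S1 =
  0`) gives an exact null generator with no S1-type dependence.

Defaults: β₀ = 2.5 1/s (≈400 ms), β_FP = 0.2 1/s per s (RTs fall by ≈30 ms from
the shortest to the longest FP), β_S1 = −0.04 (slightly faster responses after
exponential-type S1s), β_int_max = 0.25. The interaction asymptote was calibrated
during generator development so that the group-level learning trajectory at the
default 49-participant scale reproduces the qualitative target pattern — a
gradual rise reaching significant clusters over the last Acquisition blocks, an
abrupt return to baseline at the Transfer boundary, and a significant recovery
cluster within Transfer. The implied differential RT–FP effect (≈30 ms across
the FP range) is somewhat larger than the subtle effects typical of unique-image
designs; recovery of weaker effects is a matter of sample size, not of the
machinery tested here.

Contamination: responses are flipped with probability 0.02 (accuracy ≈98%,
comfortably above the 95% screening cut-off), and 0.5% of RTs are multiplied by
3 to emulate lapses — this yields ≈0.6–0.8% of correct trials removed by the
log-RT filter, matching the regime the exclusion rules are designed for.
Simulated RTs are constrained to exceed 100 ms (draws beyond the implied
inverse-RT range are resampled); parameter sets implying a non-positive mean
inverse RT are rejected before simulation.

What the generator does *not* emulate: sequential (trial n−1) FP effects,
asymptotic (non-linear) RT–FP curvature, slow drifts in the random effects,
non-Gaussian residual tails beyond the explicit outlier mechanism, and any
stimulus-identity effects. Pipeline validation on this generator therefore
demonstrates correctness of the estimators under the assumed model, not
robustness to these realistic deviations.

## Preprocessing

Participant screening precedes trial filtering: participants whose mean
correct-trial RT deviates more than 2.5 sample SDs from the sample mean of
participant means (two-sided), or whose overall accuracy falls below 95%, are
excluded with reasons recorded. Trial filtering then removes incorrect trials
and, per participant, trials whose log RT (natural log; the rule is scale-free)
lies strictly more than 3 SDs from that participant's mean log RT. The statistics
are computed once, on the post-accuracy-filter trials — a single pass, the
conservative reading (no re-iteration, which could cascade). With fewer than two
correct trials the SD is undefined; such participants keep their correct trials
and are flagged. A consequence of the single-pass rule worth knowing: the largest
attainable |z| in a sample of n is (n−1)/√n, so the 3 SD rule cannot remove
anything from samples smaller than 12 trials.

## Mixed-model comparison

Models are fit by **maximum likelihood** (not REML), since BICs are compared
across fixed-effects structures. The random structure is fixed for all models: a
per-participant random intercept and a correlated random FP slope. BIC is
computed as `−2·logLik + k·log(N)` with `N` the number of observations and `k`
counting fixed effects + 3 random-effect (co)variances + 1 residual variance
(the parameter-count convention is explicit in the code so comparisons are
internally consistent). Non-convergence is flagged and the optimizer restarted
(L-BFGS, then CG, then Powell); singular random-effect fits are flagged but
still reported. Evidence is summarized by the BIC approximation
`BF ≈ exp(ΔBIC/2)` with ΔBIC = BIC(simpler) − BIC(richer), so positive
differences favor including the richer model's terms; negative differences are
reported as inverse Bayes factors, and values beyond 1000 print as "> 1000"
while the exact value is retained internally.

## Rolling regression

Per participant, OLS with coefficients (Intercept, FP, S1 type, FP×S1) is solved
in every contiguous 60-trial window over the *retained* (post-filter) trials in
experiment order — excluded trials do not occupy window slots, and windows cross
block and phase boundaries. Each window's estimate is assigned to its center
trial (even windows: the left-of-middle trial, position 30 of 60; a `center`
option selects position 31), giving `n − window + 1` centers and no estimates at
the experiment's edges. Rank-deficient windows are flagged and dropped, never
regularized — a silently shrunken β would bias the time course. Δβ subtracts the
first (unflagged) center's value per participant and coefficient, so every time
course starts at exactly zero and measures change since the start of the
experiment. Window size is a parameter (40/60/120 are the conventional
sensitivity settings): smaller windows trade estimate precision for temporal
resolution.

## Cluster-based permutation inference

Participants' Δβ series are aligned on their ordinal center sequence, truncated
to the shortest series when filtering produces unequal grids (logged; no
imputation). At each center a one-sample t statistic tests the group mean
against zero (centers with zero variance — e.g. the all-zero first center — are
undefined and treated as subthreshold). Clusters are maximal runs of adjacent
centers with |t| above the two-tailed Student-t critical value at df = n − 1
(recomputed from the actual included sample, e.g. 2.01 at n = 49) and a common
sign; a sign change breaks a cluster. Cluster mass is the sum of t values in the
run. The null flips the sign of each participant's entire series independently —
the exact exchangeability null for a one-sample test of zero mean — and records
the maximum |mass| per permutation, pooling both signs (two-sided, max-statistic
familywise control). Monte-Carlo p-values use the (b+1)/(N+1) convention; for
n ≤ 12 participants all 2ⁿ sign patterns are enumerated and the p-value is the
exact proportion (which includes the identity pattern and is therefore never
zero). Tie comparisons carry a 1e-9 relative tolerance so the identity pattern
is never lost to floating-point summation-order noise. A scalar variant of the
same null (`sign_flip_ttest`) serves for non-cluster one-sample questions, e.g.
testing per-participant trend slopes.

## Power simulation

The power procedure scales the S1-type main effect and the S1×FP interaction of
a reference parameter set by a factor in (0, 1], simulates Transfer-phase
datasets (uniform FPs, interaction at asymptote) over a grid of sample sizes and
scales, and for each dataset fits the FP-only and FP×S1 models, deciding
significance by a likelihood-ratio test with df = 2 (the two dropped terms).
Power is the significant fraction among converged fits; non-converged fits are
excluded from the denominator and counted separately; each estimate carries its
binomial SE. Per-cell seeds derive deterministically from the master seed. The
reference effects come from this package's generator defaults rather than a
fitted model of archival data, so the reproducible object is the procedure and
its calibration (type-I error ≈ α at zero effect; monotone in scale and n), not
any particular published power number. Because "per-block" power is ambiguous,
both block-wise readings are exposed (`blockwise="any"` / `"all"`) alongside the
pooled test.

## Descriptive statistics

Group RT–FP tables average participant means with equal weight. Error bars are
95% Cousineau–Morey within-subject CIs: subtract each participant's mean across
the M conditions, add back the grand mean (which the normalization preserves),
and inflate the per-condition CI of the normalized data by √(M/(M−1)). Time-
course figures mark block breaks, shade centers whose window straddles the
between-phase questionnaire, and underline significant clusters; centers missing
at the start and end of the experiment are inherent to the windowing.

## Problem sizes used in the test suite

The suite exercises the full pipeline at the study scale (49 participants, 960
trials, 60-trial windows) once, and uses reduced configurations elsewhere —
10 participants × 2 twenty-trial blocks for the 200-replicate type-I-error
study (where the n ≤ 12 exhaustive null makes every p-value exact), 8
participants × 40 trials for the 200-simulation power calibration, and a 2×2
grid at 25 simulations per cell for monotonicity. These sizes give the stated
binomial tolerances their intended meaning while keeping the whole suite fast.

## Known limitations

- The BIC parameter count and the ±0.5 / centered-FP coding are conventions;
  BIC *differences* between models sharing the random structure are insensitive
  to the count convention but can shift slightly under different fixed-effect
  codings for non-factorial comparisons.
- The cluster test controls the familywise error for the *presence* of an
  effect; cluster boundaries are not confidence statements about onset/offset.
- The LRT used in the power module relies on the χ² approximation, which is
  mildly anticonservative at very small samples; the calibration test bounds
  this at the sizes used.
- Truncation-to-shortest alignment discards late centers of longer series when
  participants differ in retained-trial counts; with the default filtering
  rates this affects at most a few centers at the series end.
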