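"""Generative inverse-RT model for synthetic foreperiod data.

Reaction times are simulated on the inverse-RT scale (1/RT, in 1/s), the
same scale on which all downstream models are fit.  The mean structure of
trial *t* for participant *i* is

    y_it = (b0 + u0_i + fatigue(t)) + (b_fp + u1_i) * fp_c
           + b_s1 * s1_c + b_int(t) * fp_c * s1_c + eps_it

with ``fp_c``/``s1_c`` the shared codings of :mod:`foreprep.coding`,
``(u0_i, u1_i)`` correlated Gaussian random effects, and ``eps_it``
Gaussian residual noise.  The S1-type x FP interaction ``b_int(t)`` is
*learned*: it follows a saturating ramp over the Acquisition phase, is
suppressed ("dips") at the first Transfer trial -- emulating the effect of
the post-questionnaire instruction -- and recovers linearly.  The intercept
carries a within-block linear fatigue drift that resets at block breaks.

Contamination is explicit: responses are flipped with a small error
probability and a small fraction of RTs is inflated to emulate attentional
lapses, so the preprocessing rules have something to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import MS_PER_S, code_fp, code_s1
from .design import PHASE_ACQUISITION

#: Simulated RTs are constrained to exceed this floor (anticipations are
#: not part of the generative model); draws implying faster responses are
#: resampled.
MIN_RT_MS = 100.0


class ParameterError(ValueError):
    """Generative parameters that cannot produce valid reaction times."""


@dataclass(frozen=True)
class GenerativeParams:
    """Coefficients, schedules and noise of the synthetic inverse-RT model.

    Units: all betas are on the inverse-RT scale (1/s); FP-slope terms are
    per second of foreperiod; ``learning_rate`` is the number of
    Acquisition trials at which the interaction reaches half its
    asymptote (0 = instantly at asymptote); ``dip_depth`` is the fraction
    of the learned interaction suppressed at Transfer onset and
    ``dip_span_trials`` the number of Transfer trials over which it
    linearly recovers.
    """

    beta0: float = 2.5
    beta_fp: float = 0.2
    beta_s1: float = -0.04
    beta_int_max: float = 0.25
    learning_rate: float = 150.0
    dip_depth: float = 1.0
    dip_span_trials: int = 60
    fatigue_amp: float = -0.12
    noise_sd: float = 0.3
    subject_sd_intercept: float = 0.25
    subject_sd_fp: float = 0.08
    subject_corr: float = -0.3
    error_rate: float = 0.02
    outlier_rate: float = 0.005
    outlier_scale: float = 3.0
    seed: int | None = None

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for name in ("error_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 0.1:
                raise ParameterError(f"{name} must lie in [0, 0.1), got {v}")
        if self.subject_sd_intercept < 0 or self.subject_sd_fp < 0:
            raise ParameterError("subject-level SDs must be >= 0")
        if not -1 <= self.subject_corr <= 1:
            raise ParameterError("subject_corr must lie in [-1, 1]")
        if self.outlier_scale < 1:
            raise ParameterError("outlier_scale must be >= 1")
        if self.learning_rate < 0 or self.dip_span_trials < 0:
            raise ParameterError("schedule parameters must be >= 0")
        if not 0 <= self.dip_depth <= 1:
            raise ParameterError("dip_depth must lie in [0, 1]")

    def replace(self, **changes) -> "GenerativeParams":
        return dataclasses.replace(self, **changes)


def interaction_schedule(
    params: GenerativeParams, n_acquisition_trials: int, n_trials: int
) -> np.ndarray:
    """Per-trial value of the S1-type x FP interaction coefficient.

    Trials ``1..n_acquisition_trials`` follow the saturating ramp
    ``beta_int_max * (1 - 2**(-t / learning_rate))``; subsequent (Transfer)
    trials hold the end-of-Acquisition value, suppressed by ``dip_depth``
    at the first Transfer trial with linear recovery over
    ``dip_span_trials``.  In a Transfer-only design (no Acquisition trials)
    the interaction sits at its asymptote with no dip: the dip models the
    post-questionnaire intervention, which requires an Acquisition phase.
    """
    t = np.arange(1, n_trials + 1, dtype=float)
    if params.learning_rate <= 0:
        ramp = np.full(n_trials, params.beta_int_max)
        b_end = params.beta_int_max
    else:
        ramp = params.beta_int_max * (1.0 - 0.5 ** (t / params.learning_rate))
        b_end = params.beta_int_max * (
            1.0 - 0.5 ** (n_acquisition_trials / params.learning_rate)
        )
    if n_acquisition_trials == 0:
        return np.full(n_trials, params.beta_int_max)
    out = np.where(t <= n_acquisition_trials, ramp, b_end)
    j = t - n_acquisition_trials  # 1-based Transfer trial number
    span = max(params.dip_span_trials, 1)
    suppression = params.dip_depth * np.clip(1.0 - (j - 1) / span, 0.0, 1.0)
    out = np.where(t > n_acquisition_trials, out * (1.0 - suppression), out)
    return out


def _fatigue_drift(df: pd.DataFrame, amp: float) -> np.ndarray:
    """Within-block linear intercept drift, 0 at the first trial of each
    block and ``amp`` at the last; resets at block breaks."""
    g = df.groupby(["participant", "block"], sort=False)
    pos = g.cumcount().to_numpy(dtype=float)
    size = g["block"].transform("size").to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        frac = np.where(size > 1, pos / np.maximum(size - 1, 1), 0.0)
    return amp * frac


def deterministic_mean(design: pd.DataFrame, params: GenerativeParams) -> np.ndarray:
    """Fixed-effect mean inverse RT per trial (no random effects, no noise).

    ``design`` must be ordered by participant then trial_index.
    """
    fp_c = code_fp(design["fp_ms"])
    s1_c = code_s1(design["s1_type"].to_numpy())
    b_int = np.empty(len(design))
    for _, idx in design.groupby("participant", sort=False).indices.items():
        sub = design.iloc[idx]
        n_acq = int((sub["phase"] == PHASE_ACQUISITION).sum())
        b_int[idx] = interaction_schedule(params, n_acq, len(sub))
    fatigue = _fatigue_drift(design, params.fatigue_amp)
    return (
        params.beta0
        + fatigue
        + params.beta_fp * fp_c
        + params.beta_s1 * s1_c
        + b_int * fp_c * s1_c
    )


def simulate_rts(
    design: pd.DataFrame, params: GenerativeParams, seed: int | None = None
) -> pd.DataFrame:
    """Complete trial skeletons with simulated responses and RTs.

    Draws implying RT <= ``MIN_RT_MS`` or non-positive inverse RT are
    resampled.  Fully reproducible given ``seed`` (falling back to
    ``params.seed``).
    """
    params.validate()
    df = design.sort_values(["participant", "trial_index"], kind="stable").reset_index(
        drop=True
    )
    mu_fixed = deterministic_mean(df, params)
    if np.min(mu_fixed) <= 0:
        raise ParameterError(
            "parameters imply a non-positive mean inverse RT "
            f"(min {np.min(mu_fixed):.4f} 1/s); reduce drifts or raise beta0"
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)

    participants = df["participant"].unique()
    z = rng.standard_normal((len(participants), 2))
    r = params.subject_corr
    u0 = params.subject_sd_intercept * z[:, 0]
    u1 = params.subject_sd_fp * (r * z[:, 0] + np.sqrt(1.0 - r**2) * z[:, 1])
    u0_map = dict(zip(participants, u0))
    u1_map = dict(zip(participants, u1))

    fp_c = code_fp(df["fp_ms"])
    mu = (
        mu_fixed
        + df["participant"].map(u0_map).to_numpy()
        + df["participant"].map(u1_map).to_numpy() * fp_c
    )

    y_max = MS_PER_S / MIN_RT_MS  # inverse-RT ceiling implied by the RT floor
    y = mu + params.noise_sd * rng.standard_normal(len(df))
    if params.noise_sd > 0:
        for _ in range(1000):
            bad = (y <= 0) | (y >= y_max)
            if not bad.any():
                break
            y[bad] = mu[bad] + params.noise_sd * rng.standard_normal(int(bad.sum()))
    y = np.clip(y, 1e-9, y_max - 1e-9)

    rt_ms = MS_PER_S / y
    outlier = rng.random(len(df)) < params.outlier_rate
    rt_ms = np.where(outlier, rt_ms * params.outlier_scale, rt_ms)

    flipped = rng.random(len(df)) < params.error_rate
    side = df["s2_side"].to_numpy()
    other = np.where(side == "left", "right", "left")
    df["response"] = np.where(flipped, other, side)
    df["rt_ms"] = rt_ms
    df["correct"] = ~flipped
    return df


def simulate_experiment(
    spec, params: GenerativeParams, n_participants: int, seed: int | None = None
) -> pd.DataFrame:
    """Convenience: generate a design and simulate it in one call.

    Design order and RT noise use independent streams derived from
    ``seed`` so the marginal design is unchanged by RT-model tweaks.
    """
    from .design import generate_design

    ss = np.random.SeedSequence(seed if seed is not None else params.seed)
    s_design, s_rt = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    skeletons = generate_design(spec, n_participants, seed=s_design)
    return simulate_rts(skeletons, params, seed=s_rt)
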