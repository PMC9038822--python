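"""Participant screening, trial exclusion, and the inverse-RT response.

The exclusion pipeline is the conventional one for speeded two-choice
tasks:

1. participant screening -- drop participants whose mean correct-trial RT
   deviates more than 2.5 sample SDs from the sample mean of participant
   means, and participants below a 95% accuracy cut-off;
2. trial filtering -- drop incorrect trials, then drop trials whose log RT
   lies more than 3 SDs from that participant's mean log RT (statistics
   computed once, on the post-accuracy-filter trials: a single pass, no
   re-iteration);
3. add the analysis response ``inv_rt = 1000 / rt_ms`` (unit 1/s).

Both screening and filtering return structured reports so exclusion
decisions are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import MS_PER_S


@dataclass
class ScreenReport:
    """Outcome of sample-level participant screening."""

    participant_mean_rt: dict[int, float]
    participant_accuracy: dict[int, float]
    sample_mean: float
    sample_sd: float
    excluded: list[dict]  # {"participant", "reason", "value"}

    def excluded_ids(self) -> set:
        return {e["participant"] for e in self.excluded}

    def to_dict(self) -> dict:
        return {
            "sample_mean_rt_ms": self.sample_mean,
            "sample_sd_rt_ms": self.sample_sd,
            "participant_mean_rt_ms": {str(k): v for k, v in self.participant_mean_rt.items()},
            "participant_accuracy": {str(k): v for k, v in self.participant_accuracy.items()},
            "excluded": self.excluded,
        }


@dataclass
class FilterReport:
    """Per-participant bookkeeping of trial-level exclusions.

    ``fraction_discarded`` counts only the log-RT outlier removals among
    correct trials (the conventional "trials discarded" statistic, which
    excludes error trials from both numerator and denominator).
    """

    per_participant: pd.DataFrame
    excluded_participants: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_participant": self.per_participant.to_dict(orient="records"),
            "excluded_participants": self.excluded_participants,
        }


def screen_participants(
    trials: pd.DataFrame, rt_sd_cut: float = 2.5, acc_min: float = 0.95
) -> tuple[list, ScreenReport]:
    """Identify participants to retain for analysis.

    The RT rule is two-sided (any deviation beyond ``rt_sd_cut`` sample
    SDs); accuracy is computed over all trials.  Requires >= 3
    participants so the sample SD is defined.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    by_p = trials.groupby("participant", sort=True)
    if by_p.ngroups < 3:
        raise ValueError("participant screening requires >= 3 participants")
    mean_rt = by_p.apply(
        lambda g: g.loc[g["correct"], "rt_ms"].mean(), include_groups=False
    )
    accuracy = by_p["correct"].mean()
    sample_mean = float(mean_rt.mean())
    sample_sd = float(mean_rt.std(ddof=1))

    excluded: list[dict] = []
    for p in mean_rt.index:
        if sample_sd > 0 and np.isfinite(mean_rt[p]):
            z = abs(mean_rt[p] - sample_mean) / sample_sd
            if z > rt_sd_cut:
                excluded.append(
                    {"participant": p, "reason": "slow_mean_rt", "value": float(mean_rt[p])}
                )
        if accuracy[p] < acc_min:
            excluded.append(
                {"participant": p, "reason": "low_accuracy", "value": float(accuracy[p])}
            )
    excluded_ids = {e["participant"] for e in excluded}
    included = [p for p in mean_rt.index if p not in excluded_ids]
    report = ScreenReport(
        participant_mean_rt=mean_rt.to_dict(),
        participant_accuracy=accuracy.to_dict(),
        sample_mean=sample_mean,
        sample_sd=sample_sd,
        excluded=excluded,
    )
    return included, report


def filter_trials(
    trials: pd.DataFrame, logrt_sd_cut: float = 3.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove incorrect trials, then per-participant log-RT outliers.

    The log-RT mean/SD are computed per participant on that participant's
    correct trials in a single pass; trials with ``|log rt - mean| >
    logrt_sd_cut * SD`` are removed (strict inequality: with zero variance
    nothing is removed).  Participants with < 2 correct trials have an
    undefined SD; their correct trials are all retained and flagged.
    """
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("all rt_ms must be > 0")
    rows = []
    kept_parts = []
    for p, g in trials.groupby("participant", sort=True):
        n_in = len(g)
        correct = g[g["correct"]]
        n_incorrect = n_in - len(correct)
        sd_undefined = len(correct) < 2
        if sd_undefined:
            kept = correct
            n_out = 0
        else:
            logrt = np.log(correct["rt_ms"].to_numpy(dtype=float))
            m, s = logrt.mean(), logrt.std(ddof=1)
            keep = np.abs(logrt - m) <= logrt_sd_cut * s
            kept = correct[keep]
            n_out = int((~keep).sum())
        kept_parts.append(kept)
        rows.append(
            {
                "participant": p,
                "n_trials_in": n_in,
                "n_incorrect_removed": n_incorrect,
                "n_logrt_outliers_removed": n_out,
                "n_retained": len(kept),
                "fraction_discarded": n_out / len(correct) if len(correct) else 0.0,
                "sd_undefined": sd_undefined,
            }
        )
    report = FilterReport(per_participant=pd.DataFrame(rows))
    retained = (
        pd.concat(kept_parts, axis=0) if kept_parts else trials.iloc[0:0]
    ).reset_index(drop=True)
    return retained, report


def add_inverse_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis response ``inv_rt = 1000 / rt_ms`` (1/s).  The
    original RT column is preserved."""
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("all rt_ms must be > 0")
    out = trials.copy()
    out["inv_rt"] = MS_PER_S / out["rt_ms"]
    return out


def preprocess(
    trials: pd.DataFrame,
    rt_sd_cut: float = 2.5,
    acc_min: float = 0.95,
    logrt_sd_cut: float = 3.0,
) -> tuple[pd.DataFrame, ScreenReport, FilterReport]:
    """Full pipeline: screen participants, filter trials, add 1/RT."""
    included, screen = screen_participants(trials, rt_sd_cut=rt_sd_cut, acc_min=acc_min)
    retained, report = filter_trials(
        trials[trials["participant"].isin(included)], logrt_sd_cut=logrt_sd_cut
    )
    report.excluded_participants = screen.excluded
    return add_inverse_rt(retained), screen, report
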