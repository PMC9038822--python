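"""Descriptive outputs: RT-FP curves and coefficient time-course figures.

Group summaries weight participants equally (participant means first,
then an unweighted mean of participant means), the standard convention
for repeated-measures designs.  Error bars are 95% Cousineau-Morey
within-subject confidence intervals: data are first normalized by
removing each participant's mean (and restoring the grand mean), and the
per-condition interval is inflated by sqrt(M / (M - 1)) for M conditions
to correct the bias of the normalization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .rolling import COEFFICIENTS  # noqa: E402


def cousineau_morey_ci(
    data: pd.DataFrame,
    value: str = "rt_ms",
    participant: str = "participant",
    within: Sequence[str] = ("phase", "s1_type", "fp_ms"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-subject CI half-widths per condition.

    Requires a complete participant x condition table (no missing cells;
    no imputation is attempted).  Returns one row per condition with the
    unweighted group mean and the CI half-width.
    """
    within = list(within)
    pivot = data.pivot_table(index=participant, columns=within, values=value, aggfunc="mean")
    if pivot.isna().any().any():
        missing = pivot.isna().sum().sum()
        raise ValueError(f"incomplete design: {missing} missing participant x condition cells")
    n, m = pivot.shape
    if m < 2:
        raise ValueError("need >= 2 within-subject conditions")
    if n < 2:
        raise ValueError("need >= 2 participants")
    grand = pivot.to_numpy().mean()
    normalized = pivot.sub(pivot.mean(axis=1), axis=0) + grand
    sd = normalized.std(ddof=1)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    half = tcrit * sd / np.sqrt(n) * np.sqrt(m / (m - 1))
    out = pd.DataFrame({"mean": pivot.mean(axis=0), "ci_half": half})
    out.index.names = within if len(within) > 1 else [within[0]]
    return out.reset_index()


def rt_fp_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean RT per FP x S1 type x phase.

    Participant means are computed first and then averaged with equal
    weight.  Cells that no participant occupies appear with NaN mean and
    ``n_participants = 0``.
    """
    cell = (
        trials.groupby(["participant", "phase", "s1_type", "fp_ms"], observed=True)["rt_ms"]
        .mean()
        .reset_index()
    )
    group = (
        cell.groupby(["phase", "s1_type", "fp_ms"], observed=True)["rt_ms"]
        .agg(mean_rt="mean", n_participants="count")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [
            sorted(trials["phase"].unique()),
            sorted(trials["s1_type"].unique()),
            sorted(trials["fp_ms"].unique()),
        ],
        names=["phase", "s1_type", "fp_ms"],
    ).to_frame(index=False)
    out = full.merge(group, how="left", on=["phase", "s1_type", "fp_ms"])
    out["n_participants"] = out["n_participants"].fillna(0).astype(int)
    return out


def plot_rt_fp(trials: pd.DataFrame, path: str, alpha: float = 0.05) -> None:
    """RT-FP curves per S1 type, one panel per phase, with 95%
    Cousineau-Morey within-subject CIs."""
    phases = [p for p in ("Acquisition", "Transfer") if p in set(trials["phase"])]
    fig, axes = plt.subplots(1, max(len(phases), 1), figsize=(4.2 * max(len(phases), 1), 3.6),
                             sharey=True, squeeze=False)
    for ax, phase in zip(axes[0], phases):
        sub = trials[trials["phase"] == phase]
        ci = cousineau_morey_ci(sub, within=("s1_type", "fp_ms"), alpha=alpha)
        for s1, marker in (("E", "o"), ("A", "s")):
            row = ci[ci["s1_type"] == s1].sort_values("fp_ms")
            ax.errorbar(
                row["fp_ms"], row["mean"], yerr=row["ci_half"],
                marker=marker, capsize=3, label=f"S1$_{s1}$",
            )
        ax.set_title(phase)
        ax.set_xlabel("Foreperiod (ms)")
    axes[0][0].set_ylabel("Mean RT (ms)")
    axes[0][0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timecourses(
    timecourse: pd.DataFrame,
    clusters_by_coefficient: dict[str, list] | None = None,
    path: str = "timecourses.png",
    block_breaks: Sequence[int] | None = None,
    questionnaire_trial: int | None = None,
    window: int | None = None,
    alpha: float = 0.05,
) -> None:
    """Group-mean delta-beta per coefficient with within-subject CI
    ribbons, block-break markers, shading of centers whose window straddles
    the questionnaire, and significant-cluster annotations.

    Plotted centers necessarily exclude the first and last part of the
    experiment: a full window must exist around every center.
    """
    clusters_by_coefficient = clusters_by_coefficient or {}
    fig, axes = plt.subplots(len(COEFFICIENTS), 1, figsize=(9, 10), sharex=True)
    for ax, coef in zip(axes, COEFFICIENTS):
        sub = timecourse[(timecourse["coefficient"] == coef) & ~timecourse["flagged"]]
        if sub.empty:
            ax.set_ylabel(coef)
            continue
        wide = sub.pivot_table(index="participant", columns="center_trial",
                               values="delta_beta")
        wide = wide.dropna(axis=1)
        n, m = wide.shape
        mean = wide.mean(axis=0)
        if n >= 2 and m >= 2:
            normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
            half = (
                stats.t.ppf(1 - alpha / 2, n - 1)
                * normalized.std(ddof=0 if n < 2 else 1)
                / np.sqrt(n)
                * np.sqrt(m / (m - 1))
            )
            ax.fill_between(mean.index, mean - half, mean + half, alpha=0.3, lw=0)
        ax.plot(mean.index, mean.to_numpy(), lw=1.2)
        ax.axhline(0.0, color="k", lw=0.6)
        for b in block_breaks or ():
            ax.axvline(b, color="grey", ls="--", lw=0.7)
        if questionnaire_trial is not None and window is not None:
            ax.axvspan(questionnaire_trial - window // 2,
                       questionnaire_trial + window // 2,
                       color="gold", alpha=0.25, lw=0)
        y0 = ax.get_ylim()[0]
        for c in clusters_by_coefficient.get(coef, []):
            if getattr(c, "significant", False):
                ax.hlines(y0, c.start_center, c.end_center, lw=3, color="C3")
        ax.set_ylabel(f"$\\Delta\\beta$ {coef}")
    axes[-1].set_xlabel("Trial (window center)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
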