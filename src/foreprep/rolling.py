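"""Rolling-window regression: trial-resolved coefficient time courses.

For each participant an ordinary-least-squares model with four
coefficients -- Intercept, FP, S1 type, and FP x S1 type -- is fit in a
sliding window (default 60 trials) over the participant's retained trials
in experiment order.  Windows cross block and phase boundaries.  Each
window's coefficients are assigned to the window's center trial, so the
time course has ``n - window + 1`` points and no values at the very start
and end of the experiment.  Subtracting each coefficient's first value
yields the baselined measure (delta-beta) of how preparation changed
since the start of the experiment.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .coding import code_fp, code_s1

COEFFICIENTS = ("Intercept", "FP", "S1type", "FPxS1type")


def build_design_row(fp_ms: float, s1_type: str) -> np.ndarray:
    """Predictor vector (1, fp_c, s1_c, fp_c * s1_c) for one trial."""
    fp_c = float(code_fp(fp_ms))
    s1_c = float(code_s1(s1_type))
    return np.array([1.0, fp_c, s1_c, fp_c * s1_c])


def design_matrix(trials: pd.DataFrame) -> np.ndarray:
    """Stacked design rows for a trial table (n x 4)."""
    fp_c = code_fp(trials["fp_ms"])
    s1_c = code_s1(trials["s1_type"].to_numpy())
    return np.column_stack([np.ones(len(trials)), fp_c, s1_c, fp_c * s1_c])


def _center_offset(window: int, center: str) -> int:
    """0-based offset of the center trial within a window.

    For odd windows this is the middle trial; for even windows the
    left-of-middle trial (``center='left'``, the default) or the
    right-of-middle one (``center='right'``).
    """
    if center == "left":
        return math.ceil(window / 2) - 1
    if center == "right":
        return window // 2
    raise ValueError("center must be 'left' or 'right'")


def rolling_timecourse(
    trials: pd.DataFrame, window: int = 60, center: str = "left"
) -> pd.DataFrame:
    """Per-participant rolling-OLS coefficient time courses.

    ``trials`` must carry ``inv_rt`` (see :func:`foreprep.preprocess.
    add_inverse_rt`) and is processed per participant in ``trial_index``
    order.  Rank-deficient windows (e.g. only one S1 type present) yield
    flagged rows with NaN coefficients rather than silently biased
    numbers.  Participants with fewer retained trials than ``window``
    contribute no rows (with a warning).

    Returns a tidy frame with columns participant, center_ordinal,
    center_trial, coefficient, beta, delta_beta, window, flagged.
    """
    if window < 4:
        raise ValueError("window must be >= 4 to estimate four coefficients")
    offset = _center_offset(window, center)
    frames = []
    for p, g in trials.groupby("participant", sort=True):
        g = g.sort_values("trial_index", kind="stable")
        n = len(g)
        if n < window:
            warnings.warn(
                f"participant {p!r}: {n} trials < window {window}; "
                "empty time course"
            )
            continue
        X = design_matrix(g)
        y = g["inv_rt"].to_numpy(dtype=float)
        idx = g["trial_index"].to_numpy()
        n_centers = n - window + 1
        betas = np.full((n_centers, 4), np.nan)
        flags = np.zeros(n_centers, dtype=bool)
        for i in range(n_centers):
            beta, _, rank, _ = np.linalg.lstsq(
                X[i : i + window], y[i : i + window], rcond=None
            )
            if rank < 4:
                flags[i] = True
            else:
                betas[i] = beta
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "center_ordinal": np.repeat(np.arange(n_centers), 4),
                    "center_trial": np.repeat(idx[offset : offset + n_centers], 4),
                    "coefficient": np.tile(COEFFICIENTS, n_centers),
                    "beta": betas.ravel(),
                    "window": window,
                    "flagged": np.repeat(flags, 4),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "participant",
                "center_ordinal",
                "center_trial",
                "coefficient",
                "beta",
                "delta_beta",
                "window",
                "flagged",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    return to_delta(out)


def to_delta(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Populate ``delta_beta``: each coefficient series minus its first
    (unflagged) value, so the first element is exactly zero.  Idempotent:
    it recomputes from ``beta``."""
    out = timecourse.copy()

    def _baseline(g: pd.DataFrame) -> float:
        ok = g.loc[~g["flagged"]].sort_values("center_ordinal")
        return ok["beta"].iloc[0] if len(ok) else np.nan

    base = (
        out.groupby(["participant", "coefficient"], sort=False)
        .apply(_baseline, include_groups=False)
        .rename("baseline")
    )
    out = out.join(base, on=["participant", "coefficient"])
    out["delta_beta"] = out["beta"] - out.pop("baseline")
    return out
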