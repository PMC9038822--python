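"""Shared predictor codings for the inverse-RT models.

All model stages (generative simulation, mixed models, rolling regression)
use one fixed coding so that coefficients are directly comparable:

* foreperiod: seconds, centered at the design midpoint (750 ms), so the
  FP main effect is evaluated at the middle of the 300-1200 ms range and
  slope coefficients are in (1/s) per second of foreperiod;
* S1 type: effect-coded -0.5 (exponential, E) / +0.5 (anti-exponential, A);
* phase: effect-coded -0.5 (Acquisition) / +0.5 (Transfer).

The centering constant is fixed, never re-estimated per window, so rolling
coefficients remain comparable across the experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FP_CENTER_MS = 750.0
MS_PER_S = 1000.0

S1_CODES = {"E": -0.5, "A": 0.5}
PHASE_CODES = {"Acquisition": -0.5, "Transfer": 0.5}


def code_fp(fp_ms) -> np.ndarray:
    """Foreperiod in seconds, centered at the design midpoint."""
    return (np.asarray(fp_ms, dtype=float) - FP_CENTER_MS) / MS_PER_S


def code_s1(s1_type) -> np.ndarray:
    """Effect code for S1 type: E -> -0.5, A -> +0.5."""
    arr = np.asarray(s1_type)
    if arr.ndim == 0:
        if arr.item() not in S1_CODES:
            raise ValueError(f"unknown S1 type label: {arr.item()!r}")
        return np.float64(S1_CODES[arr.item()])
    unknown = set(np.unique(arr)) - set(S1_CODES)
    if unknown:
        raise ValueError(f"unknown S1 type label(s): {sorted(unknown)!r}")
    return pd.Series(arr).map(S1_CODES).to_numpy(dtype=float)


def code_phase(phase) -> np.ndarray:
    """Effect code for phase: Acquisition -> -0.5, Transfer -> +0.5."""
    arr = np.asarray(phase)
    unknown = set(np.unique(arr)) - set(PHASE_CODES)
    if unknown:
        raise ValueError(f"unknown phase label(s): {sorted(unknown)!r}")
    return pd.Series(arr).map(PHASE_CODES).to_numpy(dtype=float)


def add_model_codes(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``trials`` with ``fp_c``, ``s1_c`` and (if a phase
    column is present) ``phase_c`` predictor columns added."""
    out = trials.copy()
    out["fp_c"] = code_fp(out["fp_ms"])
    out["s1_c"] = code_s1(out["s1_type"].to_numpy())
    if "phase" in out.columns:
        out["phase_c"] = code_phase(out["phase"].to_numpy())
    return out
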