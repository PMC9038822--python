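"""Simulation-based power analysis for the S1-type preparation effect.

The procedure mirrors the standard mixed-model power heuristic: take a
reference generative model, scale down the effects of interest (the S1
type main effect and the S1 type x FP interaction), simulate many
Transfer-phase datasets over a grid of sample sizes and effect scales,
refit the FP-only and FP x S1 type mixed models to each, and estimate
power as the fraction of simulations in which a likelihood-ratio test
(df = 2: the two dropped terms) is significant.

Because blocks can also be analyzed separately, the block-wise criterion
is exposed with both readings: significance in *any* block or in *every*
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, generate_design
from .lmm import ModelSpec, fit_model, likelihood_ratio_test
from .preprocess import add_inverse_rt
from .simulate import GenerativeParams, simulate_rts

FULL_SPEC = ModelSpec("fp_by_s1type", ("FP", "S1type", "FP:S1type"))
REDUCED_SPEC = ModelSpec("fp_only", ("FP",))


def _default_reference_params() -> GenerativeParams:
    # Learned-asymptote configuration: the simulated Transfer phase carries
    # the fully acquired interaction, no learning ramp and no dip.
    return GenerativeParams(learning_rate=0.0, dip_depth=0.0)


def _default_transfer_design() -> DesignSpec:
    return DesignSpec(n_acquisition_blocks=0, n_transfer_blocks=2)


@dataclass
class PowerGrid:
    """Grid of sample sizes and effect scales for the power simulation."""

    n_participants_grid: Sequence[int] = (35, 40, 45)
    effect_scale_grid: Sequence[float] = (0.15, 0.20, 0.25)
    n_sims: int = 250
    alpha: float = 0.05
    seed: int = 0
    reference_params: GenerativeParams = field(default_factory=_default_reference_params)
    design: DesignSpec = field(default_factory=_default_transfer_design)

    def validate(self) -> None:
        if not len(self.n_participants_grid) or not len(self.effect_scale_grid):
            raise ValueError("grids must be non-empty")
        if any(n < 2 for n in self.n_participants_grid):
            raise ValueError("sample sizes must be >= 2")
        if any(not 0 < s <= 1 for s in self.effect_scale_grid):
            raise ValueError("effect scales must lie in (0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def scale_effects(params: GenerativeParams, scale: float) -> GenerativeParams:
    """Multiply the S1-type main effect and the S1 type x FP interaction by
    ``scale`` (0 < scale <= 1); every other parameter is untouched."""
    if not 0 < scale <= 1:
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    return params.replace(
        beta_s1=params.beta_s1 * scale, beta_int_max=params.beta_int_max * scale
    )


def _cell_seeds(master_seed: int, i: int, j: int, n_sims: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i, j))
    return ss.generate_state(2 * n_sims) % np.uint32(2**31)


def _lrt_significant(data: pd.DataFrame, alpha: float) -> bool | None:
    """LRT decision on one dataset; None signals a non-converged fit."""
    full = fit_model(data, FULL_SPEC)
    reduced = fit_model(data, REDUCED_SPEC)
    if not (full.converged and reduced.converged):
        return None
    _, _, p = likelihood_ratio_test(full, reduced)
    return p < alpha


def estimate_power(
    grid: PowerGrid, blockwise: str = "pooled", progress: bool = False
) -> pd.DataFrame:
    """Estimate power per (sample size, effect scale) cell.

    ``blockwise``: ``"pooled"`` tests the whole simulated phase at once;
    ``"any"``/``"all"`` require the block-wise LRT to be significant in at
    least one / every block.  Non-converged fits are excluded from the
    denominator and reported in ``n_nonconverged``.  Per-cell seeds are
    derived deterministically from ``grid.seed``.
    """
    if blockwise not in ("pooled", "any", "all"):
        raise ValueError("blockwise must be 'pooled', 'any' or 'all'")
    grid.validate()
    rows = []
    for i, n in enumerate(grid.n_participants_grid):
        for j, scale in enumerate(grid.effect_scale_grid):
            seeds = _cell_seeds(grid.seed, i, j, grid.n_sims)
            params = scale_effects(grid.reference_params, scale)
            n_sig = 0
            n_used = 0
            n_nonconv = 0
            for s in range(grid.n_sims):
                skeletons = generate_design(grid.design, n, seed=int(seeds[2 * s]))
                trials = simulate_rts(skeletons, params, seed=int(seeds[2 * s + 1]))
                trials = add_inverse_rt(trials[trials["correct"]])
                if blockwise == "pooled":
                    decision = _lrt_significant(trials, grid.alpha)
                else:
                    per_block = [
                        _lrt_significant(g, grid.alpha)
                        for _, g in trials.groupby("block", sort=True)
                    ]
                    if any(d is None for d in per_block):
                        decision = None
                    elif blockwise == "any":
                        decision = any(per_block)
                    else:
                        decision = all(per_block)
                if decision is None:
                    n_nonconv += 1
                    continue
                n_used += 1
                n_sig += bool(decision)
            power = n_sig / n_used if n_used else float("nan")
            se = (
                float(np.sqrt(power * (1 - power) / n_used)) if n_used else float("nan")
            )
            rows.append(
                {
                    "n_participants": n,
                    "effect_scale": scale,
                    "power": power,
                    "binomial_se": se,
                    "n_significant": n_sig,
                    "n_converged": n_used,
                    "n_nonconverged": n_nonconv,
                }
            )
            if progress:
                print(f"n={n} scale={scale}: power={power:.3f} (se {se:.3f})")
    return pd.DataFrame(rows)
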