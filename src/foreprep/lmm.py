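"""Linear mixed-model comparison on inverse RT with BIC -> Bayes factors.

Models predict inverse RT (1/s) from a subset of the fixed effects
{FP, S1 type, Phase} and their interactions, with FP entered as a
continuous linear predictor, plus a per-participant random intercept and
a correlated per-participant random FP slope.  All fits use maximum
likelihood (not REML): BICs are compared across fixed-effect structures,
which is only valid under ML.

Model evidence is summarized by the BIC approximation to the Bayes
factor, BF ~= exp(dBIC / 2): a positive BIC difference (simpler minus
richer) is evidence for including the richer model's terms, a negative
one evidence against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .coding import add_model_codes

#: Human-readable fixed-effect term names -> model-matrix columns.
TERM_COLUMNS = {
    "FP": "fp_c",
    "S1type": "s1_c",
    "Phase": "phase_c",
    "FP:S1type": "fp_c:s1_c",
    "FP:Phase": "fp_c:phase_c",
    "S1type:Phase": "s1_c:phase_c",
    "FP:S1type:Phase": "fp_c:s1_c:phase_c",
}

#: Number of random-effect (co)variance parameters: var(intercept),
#: var(FP slope), and their covariance.
N_RE_PARAMS = 3


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects structure (the random structure is fixed for all
    models: correlated per-participant intercept and FP slope)."""

    name: str
    fixed_terms: tuple[str, ...]

    def validate(self) -> None:
        present = set(self.fixed_terms)
        for term in self.fixed_terms:
            if term not in TERM_COLUMNS:
                raise ModelSpecError(f"unknown fixed-effect term {term!r}")
            parts = term.split(":")
            if len(parts) > 1:
                for k in range(1, len(parts)):
                    # every lower-order term must be present
                    from itertools import combinations

                    for sub in combinations(parts, k):
                        if ":".join(sub) not in present:
                            raise ModelSpecError(
                                f"interaction {term!r} requires lower-order "
                                f"term {':'.join(sub)!r}"
                            )

    @property
    def formula(self) -> str:
        rhs = " + ".join(TERM_COLUMNS[t] for t in self.fixed_terms) or "1"
        return f"inv_rt ~ {rhs}"


@dataclass
class LmmFit:
    """Summary of one maximum-likelihood mixed-model fit."""

    spec: ModelSpec
    n_obs: int
    k_fixed: int
    k_params: int
    llf: float
    bic: float
    params: pd.Series
    converged: bool
    singular: bool
    method: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class BayesFactor:
    """BIC-approximated Bayes factor with its evidential direction.

    ``bf`` is exp(|dBIC|/2) (always >= 1, read in the stated direction);
    ``raw`` is exp(dBIC/2) so that raw factors multiply/invert exactly.
    """

    delta_bic: float
    bf: float
    raw: float
    direction: str  # "for_inclusion" | "against_inclusion"

    def __str__(self) -> str:
        label = "BF" if self.direction == "for_inclusion" else "1/BF"
        if self.bf > 1000:
            return f"{label} > 1000"
        return f"{label} = {self.bf:.2f}"


@dataclass
class ModelComparison:
    """Two fitted models, their BIC difference, and the resulting
    Bayes factor.  ``delta_bic = bic_b - bic_a`` with ``a`` the richer
    model, so a positive value is evidence for the richer model."""

    name_a: str
    name_b: str
    bic_a: float
    bic_b: float
    delta_bic: float
    bayes_factor: BayesFactor

    @property
    def preferred(self) -> str:
        return self.name_a if self.delta_bic > 0 else self.name_b


def bic_to_bf(delta_bic: float) -> BayesFactor:
    """Convert a BIC difference into an estimated Bayes factor.

    BF = exp(delta_bic / 2); negative differences are reported as inverse
    Bayes factors (evidence against inclusion).
    """
    if not math.isfinite(delta_bic):
        raise ValueError("delta_bic must be finite")
    raw = math.exp(delta_bic / 2.0)
    direction = "for_inclusion" if delta_bic >= 0 else "against_inclusion"
    return BayesFactor(
        delta_bic=delta_bic, bf=math.exp(abs(delta_bic) / 2.0), raw=raw, direction=direction
    )


def fit_model(
    data: pd.DataFrame, spec: ModelSpec, maxiter: int = 500
) -> LmmFit:
    """Fit one mixed model by ML and summarize it.

    BIC is computed from the ML deviance as ``-2*llf + k*log(N)`` with
    ``k`` = fixed effects + 3 random-effect (co)variances + 1 residual
    variance and ``N`` the total observation count.  Non-convergence and
    singular random-effect fits are flagged, never silently ignored; the
    optimizer is restarted with alternative methods up to 3 times.
    """
    spec.validate()
    if data["participant"].nunique() < 2:
        raise ValueError("mixed-model fit requires >= 2 participants")
    if data["s1_type"].nunique() < 2:
        raise ValueError("mixed-model fit requires both S1 types")
    if "fp_c" not in data.columns:
        data = add_model_codes(data)

    model = smf.mixedlm(
        spec.formula, data, groups=data["participant"], re_formula="~fp_c"
    )
    caught: list[str] = []
    result = None
    method_used = ""
    for method in ("lbfgs", "cg", "powell"):
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                res = model.fit(reml=False, method=method, maxiter=maxiter)
            except (np.linalg.LinAlgError, ValueError) as exc:  # singular step
                caught.append(f"{method}: {exc}")
                continue
        caught.extend(str(w.message) for w in wlist)
        result = res
        method_used = method
        if res.converged and np.isfinite(res.llf):
            break
    if result is None:
        raise RuntimeError(f"all optimizers failed for model {spec.name!r}: {caught}")

    cov_re = np.asarray(result.cov_re, dtype=float)
    eigvals = np.linalg.eigvalsh(cov_re)
    singular = bool(eigvals.min() < 1e-10 * max(eigvals.max(), 1.0))
    k_fixed = len(result.fe_params)
    k = k_fixed + N_RE_PARAMS + 1
    n = int(result.nobs)
    bic = -2.0 * float(result.llf) + k * math.log(n)
    return LmmFit(
        spec=spec,
        n_obs=n,
        k_fixed=k_fixed,
        k_params=k,
        llf=float(result.llf),
        bic=bic,
        params=result.params.copy(),
        converged=bool(result.converged),
        singular=singular,
        method=method_used,
        warnings=caught,
    )


def compare_models(richer: LmmFit, simpler: LmmFit) -> ModelComparison:
    """BIC comparison of a richer model (a) against a simpler one (b).

    ``delta_bic = bic(simpler) - bic(richer)``: positive values mean the
    richer model has the lower BIC, i.e. evidence for including its extra
    terms.
    """
    delta = simpler.bic - richer.bic
    return ModelComparison(
        name_a=richer.spec.name,
        name_b=simpler.spec.name,
        bic_a=richer.bic,
        bic_b=simpler.bic,
        delta_bic=delta,
        bayes_factor=bic_to_bf(delta),
    )


def likelihood_ratio_test(full: LmmFit, reduced: LmmFit) -> tuple[float, int, float]:
    """LRT between nested ML fits: returns (statistic, df, p).

    Degrees of freedom equal the number of dropped fixed-effect terms.
    """
    df = full.k_fixed - reduced.k_fixed
    if df <= 0:
        raise ValueError("'full' must have more fixed-effect terms than 'reduced'")
    stat = 2.0 * (full.llf - reduced.llf)
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))
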