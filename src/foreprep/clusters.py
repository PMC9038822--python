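"""Cluster-based permutation inference on coefficient time courses.

Group-level inference asks, per time point, whether the baselined
coefficient (delta-beta) differs from zero across participants, while
correcting for multiple comparisons in a way that respects the temporal
structure of the series.  The procedure is the standard one-sample
cluster-mass permutation test:

1. a one-sample t statistic is computed at every window center;
2. maximal runs of adjacent centers with |t| above a cluster-forming
   threshold (the two-tailed Student-t critical value at the group df)
   and a common sign form clusters, each scored by its *mass* -- the sum
   of its t values;
3. the null distribution of the maximum absolute cluster mass is built by
   randomly flipping the sign of each participant's entire series (valid
   under the zero-mean exchangeability null), pooling positive and
   negative masses (two-sided control);
4. each observed cluster's p-value is the fraction of permutations whose
   maximum mass reaches its absolute mass.

For 12 or fewer participants the 2**n sign patterns are enumerated
exhaustively instead of sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: At or below this many participants, sign-flip enumeration is exhaustive.
EXHAUSTIVE_MAX_N = 12


@dataclass
class GroupTimecourse:
    """Participants x centers matrix of delta-beta values for one
    coefficient, aligned on a common center grid (no missing values)."""

    coefficient: str
    data: np.ndarray  # (n_participants, n_centers)
    centers: np.ndarray  # representative center trial index per column
    participants: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.centers = np.asarray(self.centers)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 participants")
        if np.isnan(self.data).any():
            raise ValueError("aligned time courses must not contain NaN")
        if self.data.shape[1] != len(self.centers):
            raise ValueError("centers must match the matrix columns")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]


@dataclass
class ClusterResult:
    """A contiguous suprathreshold run with its mass and permutation p."""

    start: int  # column index, inclusive
    end: int  # column index, inclusive
    start_center: int
    end_center: int
    sign: str  # "positive" | "negative"
    mass: float
    p_value: float | None = None
    significant: bool | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {
            "start_center": int(self.start_center),
            "end_center": int(self.end_center),
            "sign": self.sign,
            "span": self.span,
            "mass": self.mass,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def align_timecourses(
    timecourse: pd.DataFrame, coefficient: str, value: str = "delta_beta"
) -> GroupTimecourse:
    """Build a participants x centers matrix from a tidy time-course table.

    Flagged centers are dropped per participant; participants are aligned
    on their ordinal center sequence, truncated to the shortest (logged
    when truncation occurs) -- no imputation.
    """
    sub = timecourse[(timecourse["coefficient"] == coefficient) & ~timecourse["flagged"]]
    if sub.empty:
        raise ValueError(f"no unflagged centers for coefficient {coefficient!r}")
    series = {}
    centers = {}
    for p, g in sub.groupby("participant", sort=True):
        g = g.sort_values("center_ordinal")
        series[p] = g[value].to_numpy(dtype=float)
        centers[p] = g["center_trial"].to_numpy()
    lengths = {p: len(v) for p, v in series.items()}
    n_common = min(lengths.values())
    if len(set(lengths.values())) > 1:
        logger.info(
            "unequal center grids (lengths %s); truncating to %d",
            sorted(set(lengths.values())),
            n_common,
        )
    participants = sorted(series)
    data = np.vstack([series[p][:n_common] for p in participants])
    ref = centers[participants[0]][:n_common]
    return GroupTimecourse(
        coefficient=coefficient, data=data, centers=ref, participants=participants
    )


def t_series(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t per column (mean against zero) and a validity mask.

    Columns with zero sample SD have an undefined t; they are returned as
    t = 0 with ``valid = False`` and are treated as subthreshold.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.zeros(data.shape[1])
    np.divide(mean, sd / np.sqrt(n), out=t, where=valid)
    return t, valid


def critical_t(n_participants: int, alpha: float = 0.05) -> float:
    """Two-tailed Student-t critical value at df = n - 1."""
    if n_participants < 3:
        raise ValueError("need >= 3 participants for a t threshold")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n_participants - 1))


def find_clusters(
    t: np.ndarray, threshold: float, centers: np.ndarray | None = None
) -> list[ClusterResult]:
    """Maximal runs of adjacent suprathreshold t values of common sign.

    A sign change breaks a cluster even without an intervening
    subthreshold point.  ``mass`` is the sum of t values within the run.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t = np.asarray(t, dtype=float)
    if centers is None:
        centers = np.arange(len(t))
    labels = np.where(t > threshold, 1, np.where(t < -threshold, -1, 0))
    clusters: list[ClusterResult] = []
    if len(t) == 0 or not labels.any():
        return clusters
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(t)]))
    for s, e in zip(starts, ends):
        if labels[s] == 0:
            continue
        clusters.append(
            ClusterResult(
                start=int(s),
                end=int(e - 1),
                start_center=int(centers[s]),
                end_center=int(centers[e - 1]),
                sign="positive" if labels[s] > 0 else "negative",
                mass=float(t[s:e].sum()),
            )
        )
    return clusters


def _max_abs_cluster_mass(t_row: np.ndarray, threshold: float) -> float:
    labels = np.where(t_row > threshold, 1, np.where(t_row < -threshold, -1, 0))
    if not labels.any():
        return 0.0
    cs = np.concatenate(([0.0], np.cumsum(t_row)))
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(t_row)]))
    best = 0.0
    for s, e in zip(starts, ends):
        if labels[s] != 0:
            best = max(best, abs(cs[e] - cs[s]))
    return best


def _sign_matrix_exhaustive(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.int64)[:, None]
    bits = (codes >> np.arange(n)) & 1
    return (2 * bits - 1).astype(float)


def _null_max_masses(
    data: np.ndarray, signs: np.ndarray, threshold: float
) -> np.ndarray:
    """Maximum |cluster mass| of the sign-flipped t series, per permutation
    (vectorized: flipping signs leaves per-column sums of squares fixed)."""
    n = data.shape[0]
    sum_sq = (data**2).sum(axis=0)
    mean = signs @ data / n
    var = (sum_sq / n - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
    return np.array([_max_abs_cluster_mass(row, threshold) for row in t_null])


def permutation_test(
    group: GroupTimecourse,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    threshold: float | None = None,
    exhaustive: bool | None = None,
) -> list[ClusterResult]:
    """Cluster-mass permutation test of mean delta-beta against zero.

    Monte-Carlo p-values use the (b + 1) / (B + 1) convention; exhaustive
    enumeration (automatic for n <= 12 participants, overridable via
    ``exhaustive``) uses the exact proportion over all 2**n sign patterns,
    which includes the identity and is therefore never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = group.n_participants
    thr = critical_t(n, alpha) if threshold is None else threshold
    t_obs, valid = t_series(group.data)
    t_eff = np.where(valid, t_obs, 0.0)
    clusters = find_clusters(t_eff, thr, group.centers)
    if not clusters:
        return []
    use_exhaustive = (n <= EXHAUSTIVE_MAX_N) if exhaustive is None else exhaustive
    if use_exhaustive:
        logger.info("n = %d <= %d: exhaustive 2^%d sign-flip enumeration", n,
                    EXHAUSTIVE_MAX_N, n)
        signs = _sign_matrix_exhaustive(n)
        null_max = _null_max_masses(group.data, signs, thr)
        denom = float(len(signs))
        add = 0.0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null_max = _null_max_masses(group.data, signs, thr)
        denom = float(n_perm + 1)
        add = 1.0
    for c in clusters:
        # tolerance so exact ties (e.g. the identity sign pattern) are not
        # lost to floating-point summation-order differences
        tol = 1e-9 * max(1.0, abs(c.mass))
        count = float((null_max >= abs(c.mass) - tol).sum())
        c.p_value = (count + add) / denom
        c.significant = c.p_value < alpha
    return clusters


def sign_flip_ttest(
    values: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """One-sample location test against zero via sign-flip permutation.

    Returns the observed t statistic and its permutation p-value.  Used
    e.g. to test whether per-participant trend slopes of a delta-beta
    series are positive on average.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t undefined")
    t_obs = x.mean() / (sd / np.sqrt(n))
    if n <= EXHAUSTIVE_MAX_N:
        signs = _sign_matrix_exhaustive(n)
        add, denom = 0.0, float(len(signs))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        add, denom = 1.0, float(n_perm + 1)
    sum_sq = (x**2).sum()
    mean = signs @ x / n
    var = np.maximum((sum_sq / n - mean**2) * (n / (n - 1)), 1e-300)
    t_null = mean / np.sqrt(var / n)
    tol = 1e-9 * max(1.0, abs(t_obs))  # keep exact ties despite float noise
    if alternative == "two-sided":
        count = float((np.abs(t_null) >= abs(t_obs) - tol).sum())
    elif alternative == "greater":
        count = float((t_null >= t_obs - tol).sum())
    elif alternative == "less":
        count = float((t_null <= t_obs + tol).sum())
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    return float(t_obs), (count + add) / denom
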