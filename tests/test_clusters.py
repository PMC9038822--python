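"""Cluster formation, thresholds, and the sign-flip permutation null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from foreprep import (
    GroupTimecourse,
    critical_t,
    find_clusters,
    permutation_test,
    sign_flip_ttest,
    t_series,
)


def _group(data, coefficient="FPxS1type"):
    data = np.asarray(data, dtype=float)
    return GroupTimecourse(
        coefficient=coefficient,
        data=data,
        centers=np.arange(data.shape[1]),
        participants=list(range(data.shape[0])),
    )


class TestTSeries:
    def test_all_zero_center_has_undefined_t(self):
        t, valid = t_series(np.zeros((5, 3)))
        np.testing.assert_allclose(t, 0.0)
        assert not valid.any()

    def test_symmetric_values_cancel(self):
        data = np.array([[1.0], [1.0], [1.0], [1.0], [-1.0], [-1.0], [-1.0], [-1.0]])
        t, valid = t_series(data)
        assert t[0] == pytest.approx(0.0)
        assert valid[0]

    def test_hand_computed_t(self):
        vals = np.array([0.2, 0.3, 0.4, 0.5])
        t, valid = t_series(vals[:, None])
        expected = vals.mean() / (vals.std(ddof=1) / math.sqrt(4))
        assert t[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.35 / (np.std(vals, ddof=1) / 2))


class TestCriticalT:
    def test_study_sample_threshold(self):
        assert round(critical_t(49), 2) == 2.01

    def test_normal_limit(self):
        assert round(critical_t(10_000_000), 2) == 1.96

    def test_small_sample_against_quadrature_oracle(self):
        """Independent oracle: invert the numerically integrated Student-t
        density (df = 3) rather than calling a quantile routine."""
        df = 3

        def t_pdf(x):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        def cdf(x):
            return 0.5 + integrate.quad(t_pdf, 0, x)[0]

        oracle = optimize.brentq(lambda x: cdf(x) - 0.975, 0.1, 50.0, xtol=1e-12)
        assert critical_t(4, alpha=0.05) == pytest.approx(oracle, abs=1e-9)

    def test_minimum_sample(self):
        with pytest.raises(ValueError):
            critical_t(2)


class TestFindClusters:
    def test_constructed_runs(self):
        t = np.array([0.0, 3.0, 3.0, 0.0, -3.0])
        found = find_clusters(t, 2.01)
        assert len(found) == 2
        pos, neg = found
        assert (pos.sign, pos.start, pos.end, pos.mass) == ("positive", 1, 2, 6.0)
        assert (neg.sign, neg.start, neg.end, neg.mass) == ("negative", 4, 4, -3.0)
        assert pos.span == 2 and neg.span == 1

    def test_subthreshold_series_is_empty(self):
        assert find_clusters(np.array([1.0, -1.5, 0.3]), 2.0) == []

    def test_sign_change_breaks_adjacency(self):
        found = find_clusters(np.array([3.0, -3.0, 3.0]), 2.0)
        assert [c.sign for c in found] == ["positive", "negative", "positive"]
        assert all(c.span == 1 for c in found)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            find_clusters(np.array([1.0]), 0.0)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=40),
        st.floats(0.5, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_against_scalar_scan_oracle(self, values, thr):
        """Cluster spans and masses match a plain left-to-right scan."""
        t = np.array(values)
        expected = []
        cur = None  # (sign, start, mass)
        for i, v in enumerate(t):
            s = 1 if v > thr else (-1 if v < -thr else 0)
            if cur is not None and (s == 0 or s != cur[0]):
                expected.append(cur)
                cur = None
            if s != 0:
                cur = (s, cur[1], cur[2] + v, i) if cur else (s, i, v, i)
        if cur is not None:
            expected.append(cur)
        found = find_clusters(t, thr)
        assert len(found) == len(expected)
        for c, (sign, start, mass, end) in zip(found, expected):
            assert c.start == start and c.end == end
            assert c.mass == pytest.approx(mass)
            assert c.sign == ("positive" if sign > 0 else "negative")
            # every member is suprathreshold with the cluster's sign
            seg = t[c.start : c.end + 1]
            assert (np.abs(seg) > thr).all()
            assert (np.sign(seg) == sign).all()


@pytest.fixture
def effect_group():
    """4 participants x 6 centers with a genuine mid-series effect,
    calibrated so the exhaustive p-value is interior (not 0 or 1)."""
    rng = np.random.default_rng(12)
    data = rng.normal(0.0, 1.0, size=(4, 6))
    data[:, 2:5] += 2.0
    return _group(data)


class TestPermutationTest:
    def test_exhaustive_matches_monte_carlo(self, effect_group):
        """At n = 4 the exact 2^4-pattern null and a 10,000-draw
        Monte-Carlo null agree within 3 binomial SEs."""
        exact = permutation_test(effect_group, alpha=0.05)
        mc = permutation_test(
            effect_group, n_perm=10_000, alpha=0.05, seed=99, exhaustive=False
        )
        assert len(exact) == len(mc) >= 1
        for ce, cm in zip(exact, mc):
            assert (ce.start, ce.end, ce.sign) == (cm.start, cm.end, cm.sign)
            assert 0 < ce.p_value <= 1
            se = math.sqrt(ce.p_value * (1 - ce.p_value) / 10_000)
            assert abs(cm.p_value - ce.p_value) <= 3 * se + 2e-4

    def test_all_zero_matrix_yields_no_clusters(self):
        assert permutation_test(_group(np.zeros((6, 8)))) == []

    def test_participant_relabeling_invariance(self, effect_group):
        shuffled = _group(effect_group.data[::-1].copy())
        a = permutation_test(effect_group)
        b = permutation_test(shuffled)
        assert [(c.mass, c.p_value) for c in a] == [(c.mass, c.p_value) for c in b]

    def test_time_reversal_invariance(self, effect_group):
        reversed_group = _group(effect_group.data[:, ::-1].copy())
        a = permutation_test(effect_group)
        b = permutation_test(reversed_group)
        assert sorted(round(c.mass, 9) for c in a) == sorted(round(c.mass, 9) for c in b)
        assert sorted(c.p_value for c in a) == sorted(c.p_value for c in b)

    def test_monte_carlo_reproducible_and_converging(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, size=(8, 10))
        data[:, 3:7] += 1.2
        g = _group(data)
        exact = permutation_test(g)  # n = 8 -> exhaustive
        p_exact = exact[0].p_value
        errs = []
        for n_perm in (500, 8000):
            mc = [
                permutation_test(g, n_perm=n_perm, seed=s, exhaustive=False)[0].p_value
                for s in (1, 2, 3)
            ]
            errs.append(np.mean([abs(p - p_exact) for p in mc]))
        assert errs[1] < errs[0]  # Monte-Carlo error shrinks with more draws
        again = permutation_test(g, n_perm=500, seed=1, exhaustive=False)
        assert again[0].p_value == pytest.approx(
            permutation_test(g, n_perm=500, seed=1, exhaustive=False)[0].p_value
        )

    def test_undefined_centers_treated_subthreshold(self):
        data = np.ones((5, 3))
        data[:, 1] = [2.0, 1.5, 2.5, 1.0, 3.0]
        # columns 0 and 2 have zero variance -> no t, no cluster there
        res = permutation_test(_group(data), threshold=1.0)
        for c in res:
            assert c.start == c.end == 1


class TestSignFlipTtest:
    def test_strong_positive_effect(self):
        t, p = sign_flip_ttest(np.array([0.5, 0.6, 0.4, 0.7, 0.5, 0.65, 0.55, 0.45]))
        assert t > 0
        assert p == pytest.approx(2 / 256)  # only the two all-plus/all-minus flips tie

    def test_null_is_calibrated(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            _, p = sign_flip_ttest(rng.normal(0, 1, size=10))
            ps.append(p)
        frac = np.mean([p < 0.05 for p in ps])
        assert frac <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / 200)

    def test_one_sided_alternatives(self):
        x = np.array([0.5, 0.6, 0.4, 0.7, 0.5])
        t, p_greater = sign_flip_ttest(x, alternative="greater")
        _, p_less = sign_flip_ttest(x, alternative="less")
        assert p_greater < p_less
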