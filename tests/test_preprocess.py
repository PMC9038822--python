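"""Participant screening and trial-exclusion rules against hand-computed
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foreprep import add_inverse_rt, filter_trials, screen_participants

from conftest import make_trials


def _participant_block(participant, rts, correct=None, n_offset=0):
    correct = correct if correct is not None else [True] * len(rts)
    return [
        {"participant": participant, "trial_index": n_offset + i + 1,
         "rt_ms": rt, "correct": c,
         "response": "left" if c else "right"}
        for i, (rt, c) in enumerate(zip(rts, correct))
    ]


class TestScreenParticipants:
    def test_homogeneous_sample_fully_included(self):
        rows = []
        for p in range(1, 6):
            rows += _participant_block(p, [400, 410, 420, 390])
        included, report = screen_participants(make_trials(rows))
        assert included == [1, 2, 3, 4, 5]
        assert report.excluded == []

    def test_extreme_mean_rt_excluded_with_hand_zscore_oracle(self):
        """One of ten participants shifted far out; the exclusion decision
        must match z-scores hand-computed from the ten participant means."""
        rng = np.random.default_rng(0)
        rows = []
        base_means = []
        for p in range(1, 10):
            rts = 400 + 10 * rng.standard_normal(20)
            base_means.append(rts.mean())
            rows += _participant_block(p, rts)
        # place participant 10 at +10 sample SDs of the 9 clean means
        m9, s9 = np.mean(base_means), np.std(base_means, ddof=1)
        shifted = np.full(20, m9 + 10 * s9)
        rows += _participant_block(10, shifted)
        trials = make_trials(rows)
        included, report = screen_participants(trials, rt_sd_cut=2.5)

        # independent oracle: plain mean/SD over the 10 participant means
        means = [trials[(trials.participant == p) & trials.correct].rt_ms.mean()
                 for p in range(1, 11)]
        mu, sd = np.mean(means), np.std(means, ddof=1)
        oracle_excluded = [p for p in range(1, 11)
                           if abs(means[p - 1] - mu) / sd > 2.5]
        assert oracle_excluded == [10]
        assert [e["participant"] for e in report.excluded] == [10]
        assert report.excluded[0]["reason"] == "slow_mean_rt"
        assert included == list(range(1, 10))

    def test_accuracy_below_cutoff_excluded(self):
        rows = []
        for p in (1, 2):
            rows += _participant_block(p, [400] * 100)
        # participant 3: accuracy 94/100 = 0.94 < 0.95
        correct = [True] * 94 + [False] * 6
        rows += _participant_block(3, [400] * 100, correct)
        included, report = screen_participants(make_trials(rows), acc_min=0.95)
        assert {e["participant"]: e["reason"] for e in report.excluded} == {
            3: "low_accuracy"
        }
        assert included == [1, 2]

    def test_requires_three_participants(self):
        rows = _participant_block(1, [400]) + _participant_block(2, [400])
        with pytest.raises(ValueError, match=">= 3 participants"):
            screen_participants(make_trials(rows))
        with pytest.raises(ValueError, match="empty"):
            screen_participants(make_trials([]).reindex(columns=["participant"]))


class TestFilterTrials:
    def test_log_rt_outlier_removed_with_hand_oracle(self):
        """A single extreme RT among many ordinary ones is removed, and
        the decision matches hand-computed log-RT z-scores.  (The sample
        must be large enough that one outlier cannot dominate the SD: the
        largest attainable |z| in a sample of n is (n-1)/sqrt(n), so a
        3 SD rule needs n >= 12 to remove anything in one pass.)"""
        rts = [390, 395, 400, 402, 405, 408, 410, 395, 398, 403,
               401, 399, 407, 396, 404, 400, 402, 398, 406, 394, 20000]
        trials = make_trials(_participant_block(1, rts))
        retained, report = filter_trials(trials, logrt_sd_cut=3)
        # hand-computed log-RT z-scores identify exactly the 20000 ms trial
        logrt = np.log(rts)
        z = np.abs(logrt - logrt.mean()) / logrt.std(ddof=1)
        assert (z > 3).sum() == 1 and z.argmax() == len(rts) - 1
        assert len(retained) == len(rts) - 1
        assert 20000 not in retained["rt_ms"].to_numpy()
        row = report.per_participant.iloc[0]
        assert row["n_logrt_outliers_removed"] == 1
        assert row["fraction_discarded"] == pytest.approx(1 / len(rts))

    def test_zero_variance_removes_nothing(self):
        trials = make_trials(_participant_block(1, [400] * 8))
        retained, _ = filter_trials(trials)
        assert len(retained) == 8

    def test_incorrect_trials_removed_first_regardless_of_rt(self):
        correct = [True] * 9 + [False]
        trials = make_trials(_participant_block(1, [400] * 10, correct))
        retained, report = filter_trials(trials)
        assert len(retained) == 9
        row = report.per_participant.iloc[0]
        assert row["n_incorrect_removed"] == 1
        assert row["n_logrt_outliers_removed"] == 0

    def test_bookkeeping_identity(self, small_trials):
        # contaminate a copy so all three categories occur
        trials = small_trials.copy()
        trials.loc[trials.index[:3], "correct"] = False
        trials.loc[trials.index[5], "rt_ms"] = 60000.0
        retained, report = filter_trials(trials)
        per = report.per_participant
        assert (
            per["n_trials_in"]
            == per["n_retained"] + per["n_incorrect_removed"]
            + per["n_logrt_outliers_removed"]
        ).all()
        assert len(retained) == per["n_retained"].sum()

    def test_fewer_than_two_correct_trials_flagged_and_retained(self):
        trials = make_trials(
            _participant_block(1, [300, 1200], [True, False])
            + _participant_block(2, [400] * 5, n_offset=2)
        )
        retained, report = filter_trials(trials)
        row = report.per_participant.set_index("participant").loc[1]
        assert bool(row["sd_undefined"])
        assert row["n_retained"] == 1
        assert (retained.groupby("participant").size() == [1, 5]).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_row_order_never_changes_exclusions(self, seed):
        rng = np.random.default_rng(seed)
        rts = np.exp(rng.normal(6, 0.3, size=30))
        rts[0] *= 50  # ensure something to exclude
        correct = rng.random(30) > 0.1
        trials = make_trials(_participant_block(1, rts, list(correct))
                             + _participant_block(2, rts[::-1], n_offset=30))
        shuffled = trials.sample(frac=1.0, random_state=seed)
        kept_a, _ = filter_trials(trials)
        kept_b, _ = filter_trials(shuffled)
        key = ["participant", "trial_index"]
        assert set(map(tuple, kept_a[key].to_numpy())) == set(
            map(tuple, kept_b[key].to_numpy())
        )


class TestInverseRt:
    @pytest.mark.parametrize("rt, expected", [(500.0, 2.0), (1000.0, 1.0), (250.0, 4.0)])
    def test_arithmetic(self, rt, expected):
        out = add_inverse_rt(make_trials([{"rt_ms": rt}]))
        assert out["inv_rt"].iloc[0] == pytest.approx(expected)
        assert out["rt_ms"].iloc[0] == rt  # original preserved

    def test_round_trip(self):
        rts = [213.0, 333.3, 987.6]
        out = add_inverse_rt(make_trials([{"rt_ms": r} for r in rts]))
        np.testing.assert_allclose(1000.0 / out["inv_rt"], rts)

    def test_rejects_nonpositive_rt(self):
        with pytest.raises(ValueError):
            add_inverse_rt(make_trials([{"rt_ms": 0.0}]))
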