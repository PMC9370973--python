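import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppgqc import activity as act
from ppgqc.exceptions import IntegrityError, ParameterError
from ppgqc.io import PULSE_TABLE_COLUMNS


class TestMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected", [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((1, 2, 2), 3.0)]
    )
    def test_pythagorean(self, xyz, expected):
        x, y, z = ([v] for v in xyz)
        assert act.acc_magnitude(x, y, z) == pytest.approx([expected])

    def test_length_mismatch(self):
        with pytest.raises(IntegrityError):
            act.acc_magnitude([1, 2], [1], [1, 2])


class TestEpochSigma:
    def test_constant_epoch_zero(self):
        assert act.epoch_sigma(np.full(320, 0.7), 64.0) == pytest.approx([0.0])

    def test_alternating_unit(self):
        A = np.tile([1.0, -1.0], 160)
        assert act.epoch_sigma(A, 64.0) == pytest.approx([1.0])

    def test_matches_population_formula(self):
        rng = np.random.default_rng(3)
        A = rng.random(320)
        # brute-force population sd oracle
        mu = A.sum() / len(A)
        sigma = np.sqrt(((A - mu) ** 2).sum() / len(A))
        assert act.epoch_sigma(A, 64.0) == pytest.approx([sigma], abs=1e-12)

    def test_trailing_partial_epoch_discarded(self):
        A = np.concatenate([np.zeros(320), np.ones(100)])
        assert len(act.epoch_sigma(A, 64.0)) == 1

    def test_empty_rejected(self):
        with pytest.raises(IntegrityError):
            act.epoch_sigma([], 64.0)


class TestActivityIndex:
    def test_twelve_halves(self):
        assert act.activity_index(np.full(12, 0.5)) == pytest.approx([6.0])

    def test_two_zero_minutes(self):
        assert act.activity_index(np.zeros(24)) == pytest.approx([0.0, 0.0])

    def test_arithmetic_sum(self):
        sigmas = 0.01 * np.arange(1, 13)
        assert act.activity_index(sigmas) == pytest.approx([0.78])

    def test_sum_decomposition(self):
        rng = np.random.default_rng(1)
        sigmas = rng.random(35)  # 2 complete minutes + partial
        aind = act.activity_index(sigmas)
        assert aind.sum() == pytest.approx(sigmas[:24].sum(), abs=1e-9)


class TestActivityRanges:
    def test_octet_quartiles(self):
        values = np.arange(1.0, 9.0)
        bounds = act.define_activity_ranges(values)
        # type-7 linear interpolation oracle
        assert bounds == pytest.approx(np.percentile(values, [25, 50, 75]))
        ranges = [act.assign_range(v, bounds) for v in values]
        assert [ranges.count(r) for r in range(4)] == [2, 2, 2, 2]

    def test_identical_values_collapse_to_ar0(self):
        bounds = act.define_activity_ranges(np.full(10, 0.3))
        assert act.assign_range(0.3, bounds) == 0

    def test_monotone_boundaries(self):
        values = np.concatenate(
            [np.linspace(0, 0.04, 30), np.linspace(0.4, 1.3, 30), [6.7]]
        )
        bounds = act.define_activity_ranges(values)
        assert (np.diff(bounds) >= 0).all()

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            act.define_activity_ranges([1.0, 2.0, 3.0])

    def test_bracket_conventions(self):
        bounds = np.array([1.0, 2.0, 3.0])
        assert act.assign_range(0.0, bounds) == 0   # closed lower interval
        assert act.assign_range(1.0, bounds) == 0   # right-closed at Q1
        assert act.assign_range(3.0001, bounds) == 3

    def test_pooled_assignment_quarters(self, mini_cohort):
        from ppgqc.pipeline import process_recording

        profiles = [process_recording(r).profile for r in mini_cohort.recordings]
        pooled = np.concatenate([p.a_index for p in profiles])
        bounds = act.define_activity_ranges(pooled)
        ranges = np.array([act.assign_range(v, bounds) for v in pooled])
        frac = np.bincount(ranges, minlength=4) / len(ranges)
        assert frac == pytest.approx([0.25] * 4, abs=0.07)


def test_scaling_monotonicity():
    """Scaling the ACC channels by c > 0 scales sigma and the index by c
    (all steps through the index are homogeneous of degree 1)."""
    rng = np.random.default_rng(2)
    A = rng.random(64 * 60)
    s1 = act.epoch_sigma(A, 64.0)
    s3 = act.epoch_sigma(3.0 * A, 64.0)
    assert s3 == pytest.approx(3.0 * s1, rel=1e-9)
    assert act.activity_index(s3) == pytest.approx(3.0 * act.activity_index(s1), rel=1e-9)


def _synthetic_pulse_table(n, minutes, rng):
    feet = np.sort(rng.choice(minutes * 60 * 64, size=n, replace=False))
    return pd.DataFrame(
        {
            "subject_id": "A",
            "pulse_index": np.arange(n),
            "foot_sample": feet,
            "peak_sample": feet + 10,
            "next_foot_sample": feet + 40,
            "start_time_s": feet / 64.0,
            "activity_index": np.nan,
            "activity_range": np.nan,
        },
        columns=PULSE_TABLE_COLUMNS,
    )


class TestAssignPulseRanges:
    def test_minute_of_foot(self):
        profile = act.ActivityProfile("A", np.zeros(24), np.array([0.1, 5.0]))
        bounds = np.array([0.5, 1.0, 2.0])
        table = _synthetic_pulse_table(10, 2, np.random.default_rng(0))
        out = act.assign_pulse_ranges(table, profile, bounds)
        minute = (out["foot_sample"] // (60 * 64)).astype(int)
        assert (out.loc[minute == 0, "activity_range"] == 0).all()
        assert (out.loc[minute == 1, "activity_range"] == 3).all()

    def test_pulse_before_recording_rejected(self):
        profile = act.ActivityProfile("A", np.zeros(12), np.array([0.1]))
        table = _synthetic_pulse_table(3, 1, np.random.default_rng(0))
        with pytest.raises(IntegrityError):
            act.assign_pulse_ranges(table, profile, np.array([1, 2, 3]), 1e9)


class TestStratifiedSample:
    def _table(self, per_ar=150, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for ar in range(4):
            t = _synthetic_pulse_table(per_ar, 30, rng)
            t["activity_range"] = ar
            t["pulse_index"] = np.arange(per_ar) + ar * per_ar
            t["foot_sample"] = t["foot_sample"] + ar  # keep keys unique
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_quota_of_400(self):
        out = act.stratified_sample(self._table(), per_range=100, seed=4)
        assert len(out) == 400
        assert (out.groupby("activity_range").size() == 100).all()

    def test_deterministic_under_seed(self):
        table = self._table()
        a = act.stratified_sample(table, per_range=100, seed=9)
        b = act.stratified_sample(table, per_range=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_exact_stratum_taken_whole(self):
        table = self._table(per_ar=100)
        out = act.stratified_sample(table, per_range=100, seed=1)
        assert len(out) == 400

    def test_short_stratum_warns(self):
        table = self._table(per_ar=30)
        with pytest.warns(UserWarning, match="taking all"):
            out = act.stratified_sample(table, per_range=100, seed=1)
        assert len(out) == 120
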