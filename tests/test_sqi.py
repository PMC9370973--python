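import numpy as np
import pytest
from scipy import stats

from ppgqc import sqi
from ppgqc.preprocess import Pulse, znorm_pulse

FS = 64.0


def _two_wave_pulse(n=64, dia_ratio=0.4, rng=None, noise=0.0):
    t = np.linspace(0, 1, n, endpoint=False)
    x = np.exp(-0.5 * ((t - 0.3) / 0.1) ** 2)
    x = x + dia_ratio * np.exp(-0.5 * ((t - 0.65) / 0.16) ** 2)
    if noise and rng is not None:
        x = x + noise * rng.standard_normal(n)
    return x


def _as_pulse(x, foot=0):
    return Pulse(
        subject_id="A",
        samples_filtered=np.asarray(x, dtype=float),
        samples_norm=znorm_pulse(x),
        foot_sample=foot,
        peak_sample=foot + int(np.argmax(x)),
        next_foot_sample=foot + len(x),
        fs=FS,
    )


class TestSignalSimilarity:
    def test_identical(self):
        x = _two_wave_pulse()
        assert sqi.signal_similarity(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = _two_wave_pulse()
        assert sqi.signal_similarity(x, -x) == pytest.approx(-1.0)

    def test_resampled_pair_matches_hand_pearson(self):
        cur = np.array([0.0, 1.0, 0.0])
        prev = np.array([0.0, 1.0, 0.0, 0.0])
        # linear interpolation of prev onto 3 points: [0, 0.5, 0]
        resampled = np.interp(np.linspace(0, 1, 3), np.linspace(0, 1, 4), prev)
        expected = np.corrcoef(cur, resampled)[0, 1]
        assert sqi.signal_similarity(cur, prev) == pytest.approx(expected)

    def test_zero_variance_floor(self):
        assert sqi.signal_similarity([1.0, 1.0, 1.0], [0.0, 1.0, 0.0]) == sqi.SIGSIM_FLOOR


class TestRelPower:
    def test_in_band_sinusoid(self):
        t = np.arange(int(4 * FS)) / FS
        assert sqi.rel_power(np.sin(2 * np.pi * 1.5 * t), FS) >= 0.9

    def test_out_of_band_sinusoid(self):
        t = np.arange(int(4 * FS)) / FS
        assert sqi.rel_power(np.sin(2 * np.pi * 5.0 * t), FS) <= 0.1

    def test_equal_power_mixture(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 1.5 * t) + np.sin(2 * np.pi * 5.0 * t)
        assert sqi.rel_power(x, FS) == pytest.approx(0.5, abs=0.1)


class TestCountLocalMaxima:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([0, 1, 0, 1, 0], 2),
            ([0, 1, 2, 3, 4], 0),      # monotone ramp
            ([0, 1, 1, 0], 1),         # plateau counts once
            ([0, 1, 1, 2, 0], 1),      # plateau on a rising flank is not a peak
            ([3, 2, 1, 2, 3], 0),
        ],
    )
    def test_plateau_rule(self, seq, expected):
        assert sqi.count_local_maxima(np.asarray(seq, dtype=float)) == expected


class TestZeroCrossRates:
    def test_alternating(self):
        x = np.tile([1.0, -1.0], 8)
        assert sqi.zero_cross_rate(x) == pytest.approx(1.0)

    def test_strictly_positive(self):
        assert sqi.zero_cross_rate(np.arange(1.0, 9.0)) == 0.0

    def test_zero_inherits_previous_sign(self):
        # 1, 0, 1 : the touch of the axis is not a crossing
        assert sqi.zero_cross_rate(np.array([1.0, 0.0, 1.0])) == 0.0

    def test_triangle_derivative_single_change(self):
        tri = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        assert sqi.first_derivative_zcr(tri) == pytest.approx(1.0 / 3.0)


class TestMomentFeatures:
    def test_against_scipy_moments(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(100)
            assert sqi.skewness(x) == pytest.approx(stats.skew(x, bias=True), abs=1e-9)
            assert sqi.kurtosis(x) == pytest.approx(
                stats.kurtosis(x, fisher=False, bias=True), abs=1e-9
            )


class TestSnrMoody:
    def test_identical_pulse_capped(self):
        x = znorm_pulse(_two_wave_pulse())
        assert sqi.snr_moody(x, x.copy()) == sqi.SNR_MOODY_CEILING_DB

    def test_matched_noise_power_near_zero_db(self):
        rng = np.random.default_rng(1)
        template = znorm_pulse(_two_wave_pulse())
        vals = []
        for _ in range(200):
            noise = rng.standard_normal(template.size)
            noise *= np.sqrt(np.mean(template**2) / np.mean(noise**2))
            vals.append(sqi.snr_moody(template + noise, template))
        assert np.mean(vals) == pytest.approx(0.0, abs=1.0)

    def test_uncorrelated_pulse_low(self):
        rng = np.random.default_rng(2)
        template = znorm_pulse(_two_wave_pulse())
        vals = [
            sqi.snr_moody(znorm_pulse(rng.standard_normal(64)), template)
            for _ in range(100)
        ]
        assert np.mean(vals) < 3.0


class TestSqiVector:
    def test_clean_pulse_with_still_acc(self):
        x = _two_wave_pulse(dia_ratio=0.4)
        pulse = _as_pulse(x)
        tracker = sqi.TemplateTracker()
        vec = sqi.compute_sqi_vector(pulse, None, np.zeros(len(x)), tracker)
        assert set(vec) == set(sqi.FEATURE_NAMES)
        assert vec["Npeaks"] == 2
        assert vec["Peak2peakACC"] == pytest.approx(0.0)
        assert vec["RelPower"] > 0.5
        assert np.isfinite(list(vec.values())).all()

    def test_noise_pulse_features(self):
        rng = np.random.default_rng(3)
        noise_pulse = _as_pulse(rng.standard_normal(64))
        other = _as_pulse(rng.standard_normal(64))
        tracker = sqi.TemplateTracker()
        vec = sqi.compute_sqi_vector(noise_pulse, other, np.zeros(64), tracker)
        assert vec["Npeaks"] > 2
        assert abs(vec["SigSim"]) < 0.5

    def test_duplicate_of_previous_pulse_sigsim_one(self):
        x = _two_wave_pulse()
        tracker = sqi.TemplateTracker()
        vec = sqi.compute_sqi_vector(_as_pulse(x), _as_pulse(x), np.zeros(64), tracker)
        assert vec["SigSim"] == pytest.approx(1.0)

    def test_affine_invariance_of_zscored_features(self):
        """Features defined on the z-scored pulse do not change when the raw
        pulse is rescaled and offset; the _noZ and window features do."""
        rng = np.random.default_rng(4)
        x = _two_wave_pulse(rng=rng, noise=0.05)
        invariant = [
            "SigSim", "Entropy", "Kurtosis", "SNR", "RelPower", "Skewness",
            "ZR", "ZDR", "Npeaks", "MedianPulse", "SNR_Moody",
        ]
        vec_a = sqi.compute_sqi_vector(
            _as_pulse(x), _as_pulse(np.roll(x, 3)), np.zeros(64), sqi.TemplateTracker()
        )
        y = 7.5 * x + 42.0
        vec_b = sqi.compute_sqi_vector(
            _as_pulse(y), _as_pulse(np.roll(y, 3)), np.zeros(64), sqi.TemplateTracker()
        )
        for name in invariant:
            assert vec_b[name] == pytest.approx(vec_a[name], abs=1e-6), name
        assert vec_b["Amplitude"] == pytest.approx(7.5 * vec_a["Amplitude"], rel=1e-9)
        assert vec_b["StdPulse_noZ"] == pytest.approx(7.5 * vec_a["StdPulse_noZ"], rel=1e-9)


def test_class_separation_on_corpus(mini_dataset):
    """On the synthetic corpus the headline indices separate the classes in
    the expected directions (medians)."""
    t = mini_dataset.table
    b, e = t[t["label"] == "B"], t[t["label"] == "E"]
    assert b["Npeaks"].median() > e["Npeaks"].median()
    assert e["SigSim"].median() > b["SigSim"].median()
    assert b["Peak2peakACC"].median() > e["Peak2peakACC"].median()
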