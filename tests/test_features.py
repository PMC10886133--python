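"""Time-domain feature oracles, set dimensionalities, matrix assembly."""

import math

import numpy as np
import pytest

from gaitfuse import (FEATURE_SETS, WindowScheme, acc_mean,
                      downsample_by_two, extract_features, feature_dimension,
                      get_feature_set, grf_index_for_window, mav, normalize01,
                      rms, ssc, wl, zc)
from gaitfuse.segmentation import count_windows, segment_recording

# Per-channel dimensionalities of the fifteen feature sets.
EXPECTED_DIMS = {
    "ACC": 3, "RMS": 1, "MAV": 1, "WL": 1, "SSC": 1, "ZC": 1,
    "R/M": 2, "R/W": 2, "M/W": 2, "R/M/W": 3, "R/W/A": 5,
    "R/M/W/S": 4, "R/M/W/A": 6, "EMG": 5, "ALL": 8,
}


def naive_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def naive_zc(x, eps=0.0):
    n = 0
    for i in range(len(x) - 1):
        if np.sign(x[i]) != np.sign(x[i + 1]) and abs(x[i] - x[i + 1]) >= eps:
            n += 1
    return n


def naive_ssc(x, eps=0.0):
    n = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= eps:
            n += 1
    return n


class TestFeatureExamples:
    @pytest.mark.parametrize("fn,x,expected", [
        (rms, [1.0, 1.0, 1.0, 1.0], 1.0),
        (rms, [0.0, 0.0, 0.0], 0.0),
        (rms, [3.0, 4.0], math.sqrt(12.5)),
        (mav, [-1.0, 2.0, -3.0], 2.0),
        (mav, [0.0, 0.0], 0.0),
        (mav, [7.0, 7.0, 7.0], 7.0),
        (wl, [0.0, 1.0, 0.0, 1.0], 3.0),
        (wl, [5.0, 5.0, 5.0], 0.0),
    ])
    def test_values(self, fn, x, expected):
        assert fn(np.asarray(x)) == pytest.approx(expected)

    def test_zc_alternating(self):
        assert zc(np.array([1.0, -1.0, 1.0, -1.0]), eps=0.0) == 3

    def test_zc_all_positive(self):
        assert zc(np.array([1.0, 2.0, 0.5, 3.0])) == 0

    def test_ssc_sawtooth(self):
        assert ssc(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), eps=0.0) == 3

    def test_ssc_monotone(self):
        assert ssc(np.array([0.0, 1.0, 2.0, 4.0])) == 0

    @pytest.mark.parametrize("fn,min_len", [
        (rms, 1), (mav, 1), (wl, 2), (zc, 2), (ssc, 3)])
    def test_short_window_rejected(self, fn, min_len):
        with pytest.raises(ValueError):
            fn(np.zeros(min_len - 1))


class TestFeatureOracles:
    def test_naive_loop_agreement(self, rng):
        """All five features match independent naive-loop oracles on
        1000 random 140-sample windows to 1e-12 relative tolerance."""
        for _ in range(1000):
            x = rng.standard_normal(140)
            lx = x.tolist()
            assert rms(x) == pytest.approx(naive_rms(lx), rel=1e-12)
            assert mav(x) == pytest.approx(naive_mav(lx), rel=1e-12)
            assert wl(x) == pytest.approx(naive_wl(lx), rel=1e-12)
            assert zc(x) == naive_zc(lx)
            assert ssc(x) == naive_ssc(lx)

    def test_amplitude_scaling(self, rng):
        x = rng.standard_normal(140)
        for a in (0.5, -3.0, 10.0):
            assert rms(a * x) == pytest.approx(abs(a) * rms(x), rel=1e-12)
            assert mav(a * x) == pytest.approx(abs(a) * mav(x), rel=1e-12)
            assert wl(a * x) == pytest.approx(abs(a) * wl(x), rel=1e-12)
            assert zc(a * x) == zc(x)
            assert ssc(a * x) == ssc(x)

    def test_zc_monotone_in_eps(self, rng):
        x = rng.standard_normal(140)
        counts = [zc(x, eps) for eps in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAccMean:
    def test_constant_zero(self):
        assert np.allclose(acc_mean(np.zeros((3, 10))), 0.0)

    def test_two_sample_axis(self):
        w = np.tile(np.array([[1.0, 3.0]]), (3, 1))
        assert np.allclose(acc_mean(w), 2.0)

    def test_full_period_sinusoid_near_zero(self):
        t = np.arange(200) / 200.0
        w = np.vstack([np.sin(2 * np.pi * t)] * 3)
        assert np.allclose(acc_mean(w), 0.0, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            acc_mean(np.empty((3, 0)))


class TestFeatureSets:
    def test_all_fifteen_dimensionalities(self):
        assert set(FEATURE_SETS) == set(EXPECTED_DIMS)
        for name, dpc in EXPECTED_DIMS.items():
            assert FEATURE_SETS[name].dim_per_channel == dpc

    @pytest.mark.parametrize("name,n_ch,total", [
        ("R/W/A", 8, 40), ("ALL", 8, 64), ("E/A", 8, 64), ("RMS", 1, 1)])
    def test_total_dimension(self, name, n_ch, total):
        assert feature_dimension(name, n_ch) == total

    def test_unknown_set_rejected(self):
        with pytest.raises(KeyError):
            get_feature_set("R/X")


@pytest.fixture(scope="module")
def one_trial(prep_dataset):
    rec = prep_dataset[3]
    cycles = segment_recording(rec, prefiltered=True)
    return rec, cycles


class TestExtractFeatures:
    def test_row_count_and_columns(self, one_trial):
        rec, cycles = one_trial
        scheme = WindowScheme(140, 10)
        m = extract_features(rec, cycles, scheme, "R/W/A")
        expected = sum(count_windows(c.duration_emg, 140, 10)
                       for c in cycles)
        assert m.values.shape == (expected, 40)

    def test_acc_set_24_columns(self, one_trial):
        rec, cycles = one_trial
        m = extract_features(rec, cycles, WindowScheme(140, 10), "ACC")
        assert m.values.shape[1] == 24

    def test_deterministic(self, one_trial):
        rec, cycles = one_trial
        scheme = WindowScheme(170, 20)
        a = extract_features(rec, cycles, scheme, "R/W/A")
        b = extract_features(rec, cycles, scheme, "R/W/A")
        assert np.array_equal(a.values, b.values)

    def test_labels_inherited(self, one_trial):
        rec, cycles = one_trial
        m = extract_features(rec, cycles, WindowScheme(170, 20), "RMS")
        assert np.all(m.labels == rec.label.id)


class TestDownsample:
    def _matrix(self, n):
        from gaitfuse.features import FeatureMatrix

        return FeatureMatrix(
            values=np.arange(n, dtype=float)[:, None],
            labels=np.zeros(n, dtype=int),
            window_starts=np.arange(n) * 10,
            cycle_ids=np.zeros(n, dtype=int),
            spec=get_feature_set("RMS"), channels=("GM",))

    @pytest.mark.parametrize("n,expected", [(4, 2), (5, 3)])
    def test_row_counts(self, n, expected):
        out = downsample_by_two(self._matrix(n))
        assert out.n_windows == expected
        assert np.array_equal(out.values[:, 0],
                              np.arange(0, n, 2, dtype=float))

    def test_distinct_grf_indices(self, prep_dataset):
        rec = prep_dataset[0]
        cycles = segment_recording(rec, prefiltered=True)
        m = extract_features(rec, cycles, WindowScheme(140, 10), "RMS")
        d = downsample_by_two(m)
        grf_idx = [grf_index_for_window(s) for s in d.window_starts]
        assert len(set(grf_idx)) == len(grf_idx)


class TestNormalize:
    def _matrix(self, col):
        from gaitfuse.features import FeatureMatrix

        col = np.asarray(col, dtype=float)
        return FeatureMatrix(
            values=col[:, None], labels=np.zeros(col.size, dtype=int),
            window_starts=np.arange(col.size),
            cycle_ids=np.zeros(col.size, dtype=int),
            spec=get_feature_set("RMS"), channels=("GM",))

    def test_full_fit(self):
        out, mins, maxs = normalize01(self._matrix([0.0, 5.0, 10.0]))
        assert np.allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert mins[0] == 0.0 and maxs[0] == 10.0

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out, _, _ = normalize01(self._matrix([3.0, 3.0, 3.0]))
        assert np.allclose(out.values, 0.0)

    def test_train_only_fit_bounds_train_rows(self, rng):
        m = self._matrix(rng.standard_normal(50))
        fit = np.arange(30)
        out, _, _ = normalize01(m, fit_rows=fit)
        assert out.values[fit].min() >= 0.0
        assert out.values[fit].max() <= 1.0

    def test_clip_flag(self):
        m = self._matrix([0.0, 1.0, 2.0, 10.0])
        out, _, _ = normalize01(m, fit_rows=np.array([0, 1, 2]), clip=True)
        assert out.values.max() <= 1.0
        out2, _, _ = normalize01(m, fit_rows=np.array([0, 1, 2]), clip=False)
        assert out2.values.max() > 1.0
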