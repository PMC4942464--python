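import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2ensemble.errors import DataError
from p2ensemble.trace_features import (
    CalciumTrace,
    NormalizedTrace,
    TraceFeatures,
    amplitude_duration_relation,
    area_under_curve,
    extract_features,
    normalize_trace,
    peak_amplitude,
    remove_outliers,
    summarize_condition,
    width_at_half_max,
)

DT = 0.5
STIM = 10.0


def make_trace(fluor, cell_id="c1", experiment_id="e1", concentration=1e-6):
    t = np.arange(len(fluor)) * DT
    return CalciumTrace(
        time=t,
        fluorescence=np.asarray(fluor, dtype=float),
        stimulus_time=STIM,
        cell_id=cell_id,
        experiment_id=experiment_id,
        concentration=concentration,
    )


def norm_from_response(response, dt=DT, stimulus_time=STIM):
    t = np.arange(len(response)) * dt
    return NormalizedTrace(
        time=t,
        response=np.asarray(response, dtype=float),
        baseline_f0=50.0,
        stimulus_time=stimulus_time,
    )


def triangle_response(n_total, peak, base_s, start=STIM, dt=DT):
    """Symmetric triangular pulse starting at `start`."""
    t = np.arange(n_total) * dt
    half = base_s / 2.0
    up = np.clip((t - start) / half, 0, None)
    down = np.clip((start + base_s - t) / half, 0, None)
    return peak * np.minimum(np.minimum(up, down), 1.0)


class TestCalciumTraceValidation:
    def test_nonuniform_time_rejected(self):
        t = np.array([0.0, 0.5, 1.5, 2.0, 10.0, 11.0])
        with pytest.raises(DataError):
            CalciumTrace(t, np.full(6, 50.0), 1.8, "c", "e", 1e-6)

    def test_nonpositive_fluorescence_rejected(self):
        with pytest.raises(DataError):
            make_trace([50.0] * 30 + [0.0] + [50.0] * 30)

    def test_needs_prestimulus_samples(self):
        t = np.arange(10) * DT + 100.0  # all after stimulus
        with pytest.raises(DataError):
            CalciumTrace(t, np.full(10, 50.0), STIM, "c", "e", 1e-6)


class TestNormalizeTrace:
    def test_constant_trace_zero_response(self):
        norm = normalize_trace(make_trace([50.0] * 100))
        assert np.allclose(norm.response, 0.0)
        assert norm.baseline_f0 == pytest.approx(50.0)

    def test_doubling_gives_one(self):
        f = np.full(100, 40.0)
        f[30:40] = 80.0
        norm = normalize_trace(make_trace(f))
        assert peak_amplitude(norm) == pytest.approx(1.0)

    def test_hand_computed_amplitude(self):
        f = np.full(100, 40.0)
        f[50] = 100.0
        norm = normalize_trace(make_trace(f))
        assert peak_amplitude(norm) == pytest.approx(1.5)  # 100/40 - 1

    def test_baseline_window_too_small(self):
        trace = make_trace([50.0] * 100)
        with pytest.raises(DataError):
            normalize_trace(trace, baseline_window=0.4)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        f = 40.0 + triangle_response(200, 30.0, 40.0)  # raw FU pulse
        t1 = extract_features(make_trace(f))
        t2 = extract_features(make_trace(f * scale))
        assert t1.amplitude == pytest.approx(t2.amplitude, rel=1e-9)
        assert t1.duration == pytest.approx(t2.duration, rel=1e-9)
        assert t1.auc == pytest.approx(t2.auc, rel=1e-9)


class TestPeakAmplitude:
    def test_flat_zero(self):
        assert peak_amplitude(norm_from_response(np.zeros(100))) == 0.0

    def test_single_pulse(self):
        r = triangle_response(100, 0.8, 20.0)
        assert peak_amplitude(norm_from_response(r)) == pytest.approx(0.8)

    def test_two_pulses_global_max(self):
        r = triangle_response(300, 0.5, 20.0) + triangle_response(300, 0.9, 20.0, start=60.0)
        assert peak_amplitude(norm_from_response(r)) == pytest.approx(0.9)

    def test_prestimulus_excluded(self):
        r = np.zeros(100)
        r[5] = 5.0  # before stimulus at t=10
        r[40] = 0.3
        assert peak_amplitude(norm_from_response(r)) == pytest.approx(0.3)


class TestWidthAtHalfMax:
    def test_triangle_half_width(self):
        # base 20 s, peak 1.0 -> FWHM = 10 s by similar triangles
        r = triangle_response(200, 1.0, 20.0)
        width, truncated = width_at_half_max(norm_from_response(r))
        assert width == pytest.approx(10.0, rel=1e-9)
        assert truncated is False

    def test_gaussian_fwhm(self):
        sigma = 4.0
        t = np.arange(400) * DT
        r = np.exp(-0.5 * ((t - 60.0) / sigma) ** 2)
        r[t < STIM] = 0.0
        width, truncated = width_at_half_max(norm_from_response(r))
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma  # 9.4187 s
        assert width == pytest.approx(expected, rel=0.01)
        assert truncated is False

    def test_plateau_truncated(self):
        r = np.zeros(100)
        r[30:] = 1.0  # rises and never decays
        t = np.arange(100) * DT
        width, truncated = width_at_half_max(norm_from_response(r))
        assert truncated is True
        assert width == pytest.approx(t[-1] - 14.75)  # crossing interpolated at 14.75 s

    def test_zero_peak_raises(self):
        with pytest.raises(DataError):
            width_at_half_max(norm_from_response(np.zeros(50)))

    def test_resampling_stability(self):
        # smooth pulse sampled at 0.25 vs 0.5 s: FWHM and AUC within 2%
        sigma = 5.0
        for dt in (0.25, 0.5):
            n = int(200 / dt)
            t = np.arange(n) * dt
            r = np.exp(-0.5 * ((t - 60.0) / sigma) ** 2)
            r[t < STIM] = 0.0
            tr = norm_from_response(r, dt=dt)
            if dt == 0.25:
                w_fine = width_at_half_max(tr)[0]
                a_fine = area_under_curve(tr)
            else:
                w_coarse = width_at_half_max(tr)[0]
                a_coarse = area_under_curve(tr)
        assert w_coarse == pytest.approx(w_fine, rel=0.02)
        assert a_coarse == pytest.approx(a_fine, rel=0.02)


class TestAreaUnderCurve:
    def test_flat_zero(self):
        assert area_under_curve(norm_from_response(np.zeros(100))) == 0.0

    def test_rectangle(self):
        r = np.zeros(200)
        t = np.arange(200) * DT
        r[(t >= 20) & (t <= 50)] = 1.0
        # trapezoid ramps half a sample on each edge; tolerance covers it
        assert area_under_curve(norm_from_response(r)) == pytest.approx(30.0, abs=0.6)

    def test_triangle(self):
        r = triangle_response(200, 1.0, 20.0)
        assert area_under_curve(norm_from_response(r)) == pytest.approx(10.0, abs=0.01)

    def test_negative_excursions_included(self):
        r = np.zeros(100)
        t = np.arange(100) * DT
        r[(t >= 20) & (t <= 30)] = -0.5
        assert area_under_curve(norm_from_response(r)) < 0


class TestRemoveOutliers:
    def test_mild_extreme_kept(self):
        # (1,1,1,1,100): sample SD 44.27, band (-67.7, 109.3) -> 100 kept
        kept, removed = remove_outliers([1, 1, 1, 1, 100])
        assert removed == []
        assert len(kept) == 5

    def test_true_outlier_removed(self):
        kept, removed = remove_outliers([1, 1, 1, 1, 1, 1, 1, 1, 1, 100])
        assert removed == [9]
        assert len(kept) == 9

    def test_identical_values(self):
        kept, removed = remove_outliers([5.0] * 10)
        assert removed == []

    def test_symmetric_small(self):
        kept, removed = remove_outliers([-1.0, 0.0, 1.0])
        assert removed == []

    def test_too_few_warns_noop(self):
        with pytest.warns(UserWarning):
            kept, removed = remove_outliers([1.0, 2.0])
        assert removed == [] and len(kept) == 2

    @given(st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        v = rng.normal(0, 1, n) + rng.exponential(2, n) * (rng.uniform(size=n) < 0.1)
        kept, removed = remove_outliers(v)
        # independent brute-force oracle
        m = v.mean()
        s = v.std(ddof=1)
        expected = [i for i in range(n) if v[i] < m - 2 * s or v[i] > m + 2 * s]
        assert removed == expected
        assert set(kept).issubset(set(v))
        assert len(kept) + len(removed) == n


def feature(amp, dur, auc, exp="e1", conc=1e-6, cell="c"):
    return TraceFeatures(
        amplitude=amp, duration=dur, auc=auc, truncated=False,
        cell_id=cell, experiment_id=exp, concentration=conc,
    )


class TestSummarizeCondition:
    def _features_for_means(self, means, exp="e1"):
        feats = []
        for i, m in enumerate(means):
            conc = 10.0 ** (-8 + i)
            for j, delta in enumerate((-0.1, 0.0, 0.1)):
                feats.append(feature(m + delta, 10.0, m * 10, exp=exp, conc=conc, cell=f"{i}{j}"))
        return feats

    def test_normalized_means(self):
        feats = self._features_for_means([2.0, 4.0, 8.0])
        summaries = summarize_condition(feats, normalize_within_experiment=True)
        amps = [s.metrics["amplitude"].mean for s in summaries]
        assert amps == pytest.approx([0.25, 0.5, 1.0])

    def test_unnormalized_identity(self):
        feats = self._features_for_means([2.0, 4.0, 8.0])
        summaries = summarize_condition(feats, normalize_within_experiment=False)
        amps = [s.metrics["amplitude"].mean for s in summaries]
        assert amps == pytest.approx([2.0, 4.0, 8.0])

    def test_two_experiments_independent(self):
        feats = self._features_for_means([2.0, 4.0], exp="e1")
        feats += self._features_for_means([10.0, 5.0], exp="e2")
        summaries = summarize_condition(feats, normalize_within_experiment=True)
        for exp in ("e1", "e2"):
            maxima = max(
                s.metrics["amplitude"].mean for s in summaries if s.experiment_id == exp
            )
            assert maxima == pytest.approx(1.0)

    def test_sem_consistent(self):
        feats = self._features_for_means([2.0])
        s = summarize_condition(feats)[0].metrics["amplitude"]
        assert s.sem == pytest.approx(s.sd / np.sqrt(s.n))

    def test_outliers_counted(self):
        # 9 cells near 2.0 plus one at 50: the extreme exceeds mean + 2 SD
        feats = [
            feature(2.0 + 0.02 * i, 10.0, 20.0, conc=1e-8, cell=str(i))
            for i in range(9)
        ]
        feats.append(feature(50.0, 10.0, 20.0, conc=1e-8, cell="out"))
        s = summarize_condition(feats)[0].metrics["amplitude"]
        assert s.n_outliers_removed == 1
        assert s.n == 9

    def test_nan_durations_dropped(self):
        feats = self._features_for_means([2.0])
        feats.append(feature(0.0, float("nan"), 0.0, conc=1e-8, cell="flat"))
        s = summarize_condition(feats)[0]
        assert s.metrics["duration"].n == 3
        assert s.metrics["amplitude"].n_outliers_removed + s.metrics["amplitude"].n == 4


class TestAmplitudeDurationRelation:
    def test_anticorrelated(self):
        cells = [feature(a, 10.0 - a, 1.0, cell=str(i)) for i, a in enumerate(np.linspace(0.1, 2, 20))]
        r, _ = amplitude_duration_relation(cells)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_exponential_recovery(self):
        amps = np.linspace(0.1, 2.0, 30)
        cells = [feature(a, 30.0 * np.exp(-2.0 * a), 1.0, cell=str(i)) for i, a in enumerate(amps)]
        _, (a_hat, b_hat) = amplitude_duration_relation(cells)
        assert a_hat == pytest.approx(30.0, rel=1e-6)
        assert b_hat == pytest.approx(-2.0, rel=1e-6)

    def test_independent_data_small_r(self):
        rng = np.random.default_rng(7)
        cells = [
            feature(x, y, 1.0, cell=str(i))
            for i, (x, y) in enumerate(zip(rng.normal(1, 0.3, 500), rng.normal(20, 5, 500)))
        ]
        r, _ = amplitude_duration_relation(cells)
        assert abs(r) < 0.15

    def test_zero_variance_raises(self):
        cells = [feature(1.0, d, 1.0, cell=str(i)) for i, d in enumerate((5.0, 6.0, 7.0))]
        with pytest.raises(DataError):
            amplitude_duration_relation(cells)

    def test_too_few_cells(self):
        with pytest.raises(DataError):
            amplitude_duration_relation([feature(1.0, 5.0, 1.0)])
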