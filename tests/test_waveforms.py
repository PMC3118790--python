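"""Waveform segmentation and the 16-statistic feature extraction."""

import numpy as np
import pytest

from benthoscape.simulate import Waveform, simulate_waveform
from benthoscape.waveforms import (
    BottomSignalLostError,
    FEATURE_COLUMNS,
    WaveformSegments,
    benthic_statistics,
    decile_shannon,
    depth_normalize,
    extract_feature_row,
    extract_feature_table,
    pca_reduce,
    segment_waveform,
    transition_statistics,
)


def _two_peak_trace(n=120, surf=10.0, ben=50.0) -> Waveform:
    t = np.arange(n, dtype=float)
    y = 40 * np.exp(-((t - surf) ** 2) / 4) + 30 * np.exp(-((t - ben) ** 2) / 18)
    return Waveform(t0=0.0, dt=1.0, intensities=y)


class TestSegmentation:
    def test_two_separated_peaks_located(self):
        seg = segment_waveform(_two_peak_trace())
        assert seg.surface[0] <= 10 <= seg.surface[1]
        assert seg.benthic[0] <= 50 <= seg.benthic[1]

    def test_monotone_decay_raises_bottom_lost(self):
        t = np.arange(100, dtype=float)
        w = Waveform(0.0, 1.0, 100 * np.exp(-t / 20))
        with pytest.raises(BottomSignalLostError):
            segment_waveform(w)

    def test_benthic_starts_after_surface_ends(self):
        seg = segment_waveform(_two_peak_trace())
        assert seg.benthic[0] > seg.surface[1]
        assert seg.surface[1] <= seg.column[0] <= seg.transition[0] <= seg.benthic[0]

    def test_idempotent(self):
        w = simulate_waveform(7.0, 0.4, 0.8, seed=5)
        assert segment_waveform(w) == segment_waveform(w)

    def test_interval_ordering_invalid_rejected(self):
        with pytest.raises(ValueError):
            WaveformSegments((0, 10), (5, 8), (8, 20), (15, 30), 0.0)


def _manual_segments(n: int, lo: int, hi: int) -> WaveformSegments:
    """Segments with an exactly chosen benthic interval for statistic tests."""
    mid = (lo + hi) // 2
    return WaveformSegments((0, 2), (2, lo - 2), (lo - 2, lo), (lo, hi), 0.0)


class TestBenthicStatistics:
    def test_symmetric_triangular_pulse_has_zero_skewness(self):
        y = np.zeros(80)
        tri = np.concatenate([np.arange(11.0), np.arange(9.0, -1.0, -1.0)])
        y[40:61] = tri
        w = Waveform(0.0, 1.0, y + 0.0)
        st = benthic_statistics(_manual_segments(80, 40, 60), w)
        assert st["ben_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_segment_conventions(self):
        y = np.zeros(80)
        y[40:61] = 3.0
        w = Waveform(0.0, 1.0, y)
        st = benthic_statistics(_manual_segments(80, 40, 60), w)
        # trapezoid of constant c over m samples spans c*(m-1)
        assert st["ben_auc"] == pytest.approx(3.0 * 20)
        assert st["ben_variance"] == 0.0
        assert st["ben_intensity_range"] == 0.0

    def test_time_range_between_extrema(self):
        y = np.zeros(80)
        y[40:61] = 5.0
        y[52] = 20.0  # max at t=52
        y[48] = 1.0   # min at t=48
        w = Waveform(0.0, 1.0, y)
        st = benthic_statistics(_manual_segments(80, 40, 60), w)
        assert st["ben_time_range"] == pytest.approx(4.0)

    def test_moments_match_naive_oracle(self, rng):
        y = np.zeros(100)
        y[50:81] = rng.uniform(0.5, 20.0, 31)
        w = Waveform(0.0, 1.0, y)
        seg = WaveformSegments((0, 2), (2, 48), (48, 50), (50, 80), 0.0)
        st = benthic_statistics(seg, w)
        s = y[50:81]
        t = np.arange(50.0, 81.0)
        assert st["ben_mean"] == pytest.approx(sum(s) / len(s), rel=1e-9)
        assert st["ben_variance"] == pytest.approx(
            sum((v - np.mean(s)) ** 2 for v in s) / len(s), rel=1e-9
        )
        assert st["ben_median"] == pytest.approx(np.sort(s)[15], rel=1e-9)
        assert st["ben_mad"] == pytest.approx(
            sum(abs(v - np.mean(s)) for v in s) / len(s), rel=1e-9
        )
        assert st["ben_min"] == pytest.approx(min(s), rel=1e-9)
        assert st["ben_max"] == pytest.approx(max(s), rel=1e-9)
        assert st["ben_intensity_range"] == pytest.approx(max(s) - min(s), rel=1e-9)
        # time-weighted skewness/kurtosis oracle (5%-of-peak trimmed mass)
        m = np.where(s >= 0.05 * s.max(), s, 0.0)
        p = m / m.sum()
        mu = sum(p * t)
        m2 = sum(p * (t - mu) ** 2)
        m3 = sum(p * (t - mu) ** 3)
        m4 = sum(p * (t - mu) ** 4)
        assert st["ben_skewness"] == pytest.approx(m3 / m2**1.5, rel=1e-9)
        assert st["ben_kurtosis"] == pytest.approx(m4 / m2**2, rel=1e-9)


class TestDecileShannon:
    def test_uniform_intensities_reach_ln10(self):
        assert decile_shannon(np.full(50, 7.0)) == pytest.approx(np.log(10))

    def test_single_dominant_decile_tends_to_zero(self):
        x = np.zeros(100)
        x[-1] = 1000.0
        # only the top decile carries mass -> entropy near 0
        assert decile_shannon(x) < 0.05

    def test_brute_force_percentile_oracle(self):
        x = np.arange(1.0, 101.0)
        # independent deciles: linear interpolation between order statistics
        sorted_x = np.sort(x)
        decs = []
        for q in range(10, 101, 10):
            pos = (q / 100) * (len(x) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            hi = min(lo + 1, len(x) - 1)
            decs.append(sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac)
        q_ = np.array(decs) / np.sum(decs)
        expected = -np.sum(q_ * np.log(q_))
        assert decile_shannon(x) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            decile_shannon(np.zeros(20))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            decile_shannon(np.ones(5))


class TestTransitionStatistics:
    def test_linear_ramp_mean_is_midpoint_value(self):
        y = np.zeros(80)
        y[30:41] = 2.0 + 0.5 * np.arange(11)  # a + b*t on the transition
        w = Waveform(0.0, 1.0, y)
        seg = WaveformSegments((0, 2), (2, 30), (30, 40), (40, 60), 0.0)
        st = transition_statistics(seg, w)
        assert st["tr_mean"] == pytest.approx(y[35], rel=1e-12)

    def test_constant_transition_variance_zero(self):
        y = np.zeros(80)
        y[30:41] = 4.0
        w = Waveform(0.0, 1.0, y)
        seg = WaveformSegments((0, 2), (2, 30), (30, 40), (40, 60), 0.0)
        st = transition_statistics(seg, w)
        assert st["tr_variance"] == 0.0
        assert st["tr_skewness"] == pytest.approx(0.0, abs=1e-12)


class TestFeatureTable:
    def test_16_feature_columns(self):
        waves = [simulate_waveform(d, 0.5, 0.5, seed=i) for i, d in enumerate([4, 8, 12])]
        table = extract_feature_table(waves, [4, 8, 12])
        assert list(table.columns) == ["sounding_id", "depth", *FEATURE_COLUMNS]
        assert len(FEATURE_COLUMNS) == 16

    def test_empty_input_gives_empty_table(self):
        table = extract_feature_table([], [])
        assert table.empty

    def test_lost_bottom_rows_excluded(self):
        t = np.arange(100, dtype=float)
        lost = Waveform(0.0, 1.0, 100 * np.exp(-t / 20))
        waves = [simulate_waveform(6.0, 0.5, 0.5, seed=1), lost,
                 simulate_waveform(9.0, 0.5, 0.5, seed=2)]
        table = extract_feature_table(waves, [6, 0, 9])
        assert len(table) == 2

    def test_skewness_decreases_with_simulator_complexity(self):
        """Module link: extracted skew mirrors the generator's complexity."""
        skews = [
            extract_feature_row(simulate_waveform(8.0, c, 0.0))["ben_skewness"]
            for c in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(skews) < 0)


class TestDepthNormalize:
    def _table(self, rng, n=40):
        waves = [simulate_waveform(d, 0.5, 0.5, seed=i)
                 for i, d in enumerate(rng.uniform(3, 14, n))]
        return extract_feature_table(waves, rng.uniform(3, 14, n))

    def test_quadratic_feature_has_zero_residuals(self, rng):
        table = self._table(rng)
        d = table["depth"]
        table["ben_mean"] = 1.0 + 2.0 * d - 0.1 * d**2
        resid = depth_normalize(table)
        assert np.allclose(resid["ben_mean"], 0.0)

    def test_residual_columns_are_centred(self, rng):
        resid = depth_normalize(self._table(rng))
        for col in FEATURE_COLUMNS:
            assert abs(resid[col].mean()) < 1e-9

    def test_five_point_parabola_oracle(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 8.0])
        # brute-force normal equations for y ~ [d^2, d, 1]
        A = np.column_stack([d**2, d, np.ones(5)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        expected = y - A @ coef
        expected = expected / expected.std()
        table = self._table(np.random.default_rng(0), n=5)
        table["depth"] = d
        table["ben_mean"] = y
        resid = depth_normalize(table)
        assert np.allclose(resid["ben_mean"], expected, atol=1e-9)


class TestPCA:
    def test_variance_threshold_and_ordering(self, rng):
        waves = [simulate_waveform(d, c, 0.5, seed=i)
                 for i, (d, c) in enumerate(zip(rng.uniform(3, 14, 60), rng.uniform(0, 1, 60)))]
        table = extract_feature_table(waves, rng.uniform(3, 14, 60))
        scores, pca = pca_reduce(depth_normalize(table), variance_kept=0.95)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-12)
        assert pca.explained_variance_ratio_.sum() >= 0.95
        assert scores.filter(like="PC").shape[1] < len(FEATURE_COLUMNS)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        waves = [simulate_waveform(d, c, 0.5, seed=i)
                 for i, (d, c) in enumerate(zip(rng.uniform(3, 14, 50), rng.uniform(0, 1, 50)))]
        table = extract_feature_table(waves, rng.uniform(3, 14, 50))
        resid = depth_normalize(table)
        _, pca = pca_reduce(resid, variance_kept=0.999999)
        X = resid[list(FEATURE_COLUMNS)].to_numpy()
        eigs = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(pca.explained_variance_, eigs[: len(pca.explained_variance_)],
                           rtol=1e-8, atol=1e-10)
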