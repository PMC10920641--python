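"""Preprocessing, windowed cross-lagged |Fisher Z| and the pseudodyad null."""

import math

import numpy as np
import pytest
from scipy import stats

from dyadsync.motion_energy import MotionEnergySeries
from dyadsync.synchrony import (
    R_CAP,
    CrossCorrConfig,
    PreprocessConfig,
    ZeroVarianceError,
    generate_pseudodyads,
    interpersonal_config,
    intrapersonal_config,
    intrapersonal_coordination,
    preprocess_series,
    pseudosynchrony_comparison,
    windowed_crosslag,
)

CAP_Z = math.atanh(R_CAP)


def naive_crosslag(a, b, cfg):
    """Independent oracle: direct pearsonr + atanh over the same grid."""
    w = cfg.window_samples
    lags = cfg.lag_grid_samples
    t0 = max(0, -int(lags.min()))
    starts = range(t0, len(a) - w - int(lags.max()) + 1, cfg.step_samples)
    out = []
    for t in starts:
        row = []
        for l in lags:
            x, y = a[t : t + w], b[t + l : t + l + w]
            if np.std(x) == 0 or np.std(y) == 0:
                row.append(np.nan)
                continue
            r = stats.pearsonr(x, y).statistic
            row.append(abs(math.atanh(np.clip(r, -R_CAP, R_CAP))))
        out.append(row)
    return np.array(out)


class TestPreprocess:
    def test_constant_series_raises(self):
        s = MotionEnergySeries(np.full(100, 7), "participant_head", 10.0)
        with pytest.raises(ZeroVarianceError):
            preprocess_series(s)

    def test_sd_scaling_normalizes(self, rng):
        s = MotionEnergySeries(rng.integers(0, 40, 200), "participant_head", 10.0)
        out = preprocess_series(s, PreprocessConfig(sd_scale=True, smooth_sec=0.0))
        assert np.std(out, ddof=1) == pytest.approx(1.0)

    def test_centered_average_with_edge_shrinkage(self):
        out = preprocess_series(
            np.array([0.0, 0, 3, 0, 0]),
            PreprocessConfig(sd_scale=False, smooth_sec=3.0),
            fps=1.0,
        )
        assert out.tolist() == [0, 1, 1, 1, 0]

    def test_length_preserved(self, rng):
        s = MotionEnergySeries(rng.integers(0, 20, 157), "participant_head", 29.95)
        assert len(preprocess_series(s)) == 157


class TestWindowedCrosslag:
    def test_self_correlation_hits_the_cap_at_lag_zero(self, rng):
        a = rng.standard_normal(400)
        m = windowed_crosslag(a, a, CrossCorrConfig(10.0, 20.0, 2.0, 10.0, 1.0))
        lag0 = list(m.lags_sec).index(0.0)
        assert np.allclose(m.values[:, lag0], CAP_Z)

    def test_matches_naive_oracle(self, rng):
        cfg = CrossCorrConfig(fps=5.0, window_sec=8.0, max_lag_sec=2.0,
                              step_sec=3.0, lag_increment_sec=1.0)
        for _ in range(5):
            a = rng.standard_normal(120)
            b = 0.5 * a + rng.standard_normal(120)
            m = windowed_crosslag(a, b, cfg)
            expected = naive_crosslag(a, b, cfg)
            assert np.allclose(m.values, expected, atol=1e-10, equal_nan=True)

    def test_delayed_copy_peaks_at_the_delay(self, rng):
        fps, k_sec = 10.0, 3.0
        a = np.cumsum(rng.standard_normal(1200))  # smooth, non-constant
        k = round(k_sec * fps)
        b = np.concatenate([rng.standard_normal(k), a[:-k]])  # b trails a by k
        m = windowed_crosslag(a, b, CrossCorrConfig(fps, 30.0, 5.0, 15.0, 1.0))
        for row in m.values:
            assert m.lags_sec[np.argmax(row)] == k_sec
            assert row.max() == pytest.approx(CAP_Z)

    def test_independent_noise_stays_below_atanh_02(self, rng):
        cfg = interpersonal_config(fps=30.0)
        for _ in range(5):
            a = rng.standard_normal(30 * 150)
            b = rng.standard_normal(30 * 150)
            assert windowed_crosslag(a, b, cfg).mean() < math.atanh(0.2)

    def test_role_swap_symmetry_on_aligned_grid(self, rng):
        # step == lag increment, so window t at lag l matches window t+l at -l
        cfg = CrossCorrConfig(fps=4.0, window_sec=10.0, max_lag_sec=2.0,
                              step_sec=2.0, lag_increment_sec=2.0)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        m_ab = windowed_crosslag(a, b, cfg)
        m_ba = windowed_crosslag(b, a, cfg)
        starts = list(m_ab.window_starts_sec)
        lags = list(m_ab.lags_sec)
        for i, t in enumerate(starts):
            for j, l in enumerate(lags):
                if (t + l) in starts:
                    i2, j2 = starts.index(t + l), lags.index(-l)
                    assert m_ab.values[i, j] == pytest.approx(m_ba.values[i2, j2])

    def test_zero_variance_window_marked_missing(self):
        a = np.zeros(100)
        a[60:] = np.arange(40)
        b = np.arange(100.0)
        cfg = CrossCorrConfig(fps=2.0, window_sec=10.0, max_lag_sec=1.0,
                              step_sec=10.0, lag_increment_sec=1.0)
        m = windowed_crosslag(a, b, cfg)
        assert np.isnan(m.values).any()
        assert (m.entries >= 0).all()

    def test_too_short_series_raises(self, rng):
        with pytest.raises(ValueError):
            windowed_crosslag(
                rng.standard_normal(50), rng.standard_normal(50),
                interpersonal_config(fps=30.0),
            )

    def test_fisher_z_entries_nonnegative(self, rng):
        a, b = rng.standard_normal(300), rng.standard_normal(300)
        m = windowed_crosslag(a, b, CrossCorrConfig(10.0, 10.0, 2.0, 5.0, 1.0))
        assert (m.entries >= 0).all()


class TestIntrapersonal:
    def test_identical_streams_at_cap(self, rng):
        x = rng.standard_normal(600)
        m = intrapersonal_coordination(x, x, fps=10.0)
        lag0 = list(m.lags_sec).index(0.0)
        assert np.allclose(m.values[:, lag0], CAP_Z)

    def test_same_code_path_as_windowed_crosslag(self, rng):
        h, b = rng.standard_normal(600), rng.standard_normal(600)
        m1 = intrapersonal_coordination(h, b, fps=10.0)
        m2 = windowed_crosslag(h, b, intrapersonal_config(10.0))
        assert np.array_equal(m1.values, m2.values, equal_nan=True)

    def test_uses_30s_windows_15s_steps(self):
        cfg = intrapersonal_config(fps=10.0)
        assert cfg.window_samples == 300
        assert cfg.step_samples == 150
        assert cfg.lag_grid_samples.max() == 50


class TestPseudodyads:
    def test_two_dyads_exhaustive_gives_the_two_crossed_pairings(self):
        ps = generate_pseudodyads(["d1", "d2"], n=None)
        assert sorted(ps.pairings) == [("d1", "d2"), ("d2", "d1")]

    def test_500_pseudodyads_from_94_none_genuine(self):
        ids = [f"d{i}" for i in range(94)]
        ps = generate_pseudodyads(ids, n=500, seed=0)
        assert len(ps) == 500
        assert all(p != a for p, a in ps.pairings)
        assert len(set(ps.pairings)) == 500  # without replacement of pairings

    def test_deterministic_under_seed(self):
        ids = [f"d{i}" for i in range(10)]
        a = generate_pseudodyads(ids, n=30, seed=42)
        b = generate_pseudodyads(ids, n=30, seed=42)
        assert a.pairings == b.pairings

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            generate_pseudodyads(["a", "b", "c"], n=7, seed=0)

    def test_single_dyad_raises(self):
        with pytest.raises(ValueError):
            generate_pseudodyads(["only"], n=None)


class _Const:
    """Minimal CrossCorrMatrix stand-in exposing mean()."""

    def __init__(self, v):
        self.v = v

    def mean(self):
        return self.v


class TestPseudosynchronyComparison:
    def test_shifted_real_values_detected(self, rng):
        real = [_Const(v) for v in rng.normal(1.0, 0.3, 50)]
        pseudo = [_Const(v) for v in rng.normal(0.0, 0.3, 50)]
        res = pseudosynchrony_comparison(real, pseudo)
        assert res.p < 0.001
        assert res.t > 0

    def test_exchangeable_sides_give_uniform_p(self, rng):
        pvals = []
        for _ in range(200):
            real = [_Const(v) for v in rng.normal(0, 1, 20)]
            pseudo = [_Const(v) for v in rng.normal(0, 1, 20)]
            pvals.append(pseudosynchrony_comparison(real, pseudo).p)
        # calibrated test: rejection rate near alpha
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= rate <= 0.12

    def test_single_dyad_raises(self):
        with pytest.raises(ValueError):
            pseudosynchrony_comparison([_Const(1.0)], [_Const(0.5), _Const(0.4)])
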