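"""Confound regression: filter responses, short-channel PCA, motion
regressors and the OLS contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from fnirsgait.confounds import (RegressorSet, build_motion_regressors, lowpass_pre,
                                 pca_short_channels, regress_confounds)
from fnirsgait.core import Kinematics, Recording
from fnirsgait.normalize import butter_gain


def _rec(data, fs=60.0, unit="micromolar", chromo=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    rows = pd.DataFrame({
        "channel": [f"S{i + 1}-D{100 + i}" for i in range(n)],
        "wavelength_nm": [np.nan] * n,
        "chromophore": chromo or ["HbO"] * n,
    })
    return Recording(data, fs, unit, rows)


def _kin(series_overrides=None, n=3600, fs=60.0, seed=0):
    rng = np.random.default_rng(seed)
    series = {
        "head_acceleration": rng.normal(size=(3, n)),
        "head_angular_acceleration": rng.normal(size=(3, n)),
        "head_neck_orientation": rng.normal(size=(3, n)),
        "body_velocity": np.abs(rng.normal(size=(1, n))),
        "body_position": rng.normal(size=(2, n)),
    }
    if series_overrides:
        series.update(series_overrides)
    return Kinematics(fs_hz=fs, series=series)


class TestLowpass:
    def test_dc_unchanged(self):
        out = lowpass_pre(_rec(np.full(3000, 2.5)))
        np.testing.assert_allclose(out.data, 2.5, atol=1e-9)

    def test_cutoff_gain_analytic(self):
        # third-order Butterworth at fc: single-pass |H| = 1/sqrt(2)
        sos = sps.butter(3, 0.5, btype="low", fs=60.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.5], fs=60.0)
        assert abs(h[0]) == pytest.approx(2 ** -0.5, rel=0.01)
        assert butter_gain(0.5, 3, 0.5, "low") == pytest.approx(2 ** -0.5)

    def test_stopband_measured_two_pass(self):
        fs, f = 60.0, 5.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * f * t)
        out = lowpass_pre(_rec(x, fs=fs))
        measured = np.ptp(out.data[0][1000:-1000]) / 2
        assert measured < butter_gain(0.5, 3, f, "low") ** 2 * 1.1
        assert measured < 1e-3  # analytic two-pass bound ~ 1e-6

    def test_type_check(self):
        with pytest.raises(TypeError):
            lowpass_pre(np.zeros(10))


class TestShortChannelPca:
    def _systemic_short(self, rank=3, n_rows=32, n=6000, seed=0, noise=0.01):
        rng = np.random.default_rng(seed)
        C = rng.normal(size=(rank, n))
        W = rng.normal(size=(n_rows, rank))
        return _rec(W @ C + noise * rng.normal(size=(n_rows, n)))

    def test_low_rank_variance_captured(self):
        regs = pca_short_channels(self._systemic_short(rank=3), k=8)
        assert regs.variance_explained > 0.99
        assert regs.k_components == 8

    def test_scores_orthogonal(self):
        regs = pca_short_channels(self._systemic_short(rank=6), k=6)
        m = regs.matrix
        gram = m.T @ m / len(m)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_zero_empty(self):
        regs = pca_short_channels(self._systemic_short(), k=0)
        assert regs.matrix.shape[1] == 0

    def test_fewer_rows_than_k_warns(self):
        rec = self._systemic_short(rank=2, n_rows=4)
        with pytest.warns(UserWarning, match="only 4"):
            regs = pca_short_channels(rec, k=8)
        assert regs.k_components == 4

    def test_all_pruned_errors(self):
        rec = self._systemic_short(n_rows=4)
        rec = rec.copy(pruned=frozenset(rec.rows["channel"]))
        with pytest.raises(ValueError):
            pca_short_channels(rec)


class TestMotionRegressors:
    def test_columns_standardized(self):
        regs = build_motion_regressors(_kin())
        assert regs.matrix.shape[1] == 9
        np.testing.assert_allclose(regs.matrix.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(regs.matrix.std(0), 1.0, atol=1e-10)

    def test_constant_orientation_dropped(self):
        kin = _kin({"head_neck_orientation": np.zeros((3, 3600))})
        with pytest.warns(UserWarning, match="zero-variance"):
            regs = build_motion_regressors(kin)
        assert regs.matrix.shape[1] == 6
        assert "head_neck_pitch" not in regs.labels

    def test_pitch_ramp_preserved(self):
        n = 3600
        kin = _kin()
        ramp = np.linspace(-20, 0, n)
        kin.series["head_neck_orientation"][1] = ramp
        regs = build_motion_regressors(kin)
        col = regs.matrix[:, regs.labels.index("head_neck_pitch")]
        assert np.corrcoef(col, ramp)[0, 1] == pytest.approx(1.0)


class TestRegression:
    def _setup(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        X = (X - X.mean(0)) / X.std(0)
        regs = RegressorSet(X, [f"r{i}" for i in range(4)])
        return rng, X, regs

    def test_y_equal_regressor_residual_zero(self):
        rng, X, regs = self._setup()
        y = 3.0 * X[:, 1]
        resid, report = regress_confounds(_rec(y), regs)
        np.testing.assert_allclose(resid.data, 0.0, atol=1e-10)
        assert report.table["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_y_untouched(self):
        rng, X, regs = self._setup()
        y = rng.normal(size=X.shape[0])
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0] # orthogonalize
        y = y - y.mean()
        resid, _ = regress_confounds(_rec(y), regs)
        np.testing.assert_allclose(resid.data[0], y, atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng, X, regs = self._setup(seed=2)
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=X.shape[0])
        resid, _ = regress_confounds(_rec(y), regs)
        for j in range(X.shape[1]):
            assert abs(np.corrcoef(resid.data[0], X[:, j])[0, 1]) < 1e-8

    def test_rank_deficient_named(self):
        rng, X, _ = self._setup()
        Xd = np.column_stack([X, X[:, 0]])
        regs = RegressorSet(Xd, [f"r{i}" for i in range(4)] + ["dup"])
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(_rec(rng.normal(size=X.shape[0])), regs)

    def test_extra_noise_regressors_never_hurt(self):
        """OLS projection property: adding columns cannot increase the
        residual variance."""
        rng, X, regs = self._setup(seed=3)
        y = X @ np.ones(4) + rng.normal(size=X.shape[0])
        _, rep_small = regress_confounds(_rec(y), regs)
        X_big = np.column_stack([X, rng.normal(size=(X.shape[0], 5))])
        regs_big = RegressorSet((X_big - X_big.mean(0)) / X_big.std(0),
                                [f"r{i}" for i in range(9)])
        _, rep_big = regress_confounds(_rec(y), regs_big)
        assert (rep_big.table["residual_variance"].iloc[0]
                <= rep_small.table["residual_variance"].iloc[0] + 1e-12)

    def test_synthetic_confound_removal(self):
        """Long channel = neural + systemic loading; regression on the
        systemic sources at least halves the RMSE to the neural part."""
        rng = np.random.default_rng(5)
        n = 6000
        C = rng.normal(size=(3, n)).cumsum(axis=1)
        C = (C - C.mean(1, keepdims=True)) / C.std(1, keepdims=True)
        neural = np.sin(2 * np.pi * 0.03 * np.arange(n) / 60)
        y = neural + np.array([1.0, -0.5, 0.3]) @ C + 0.05 * rng.normal(size=n)
        regs = RegressorSet(C.T, ["c1", "c2", "c3"])
        resid, _ = regress_confounds(_rec(y), regs)
        rmse_before = np.sqrt(np.mean((y - neural) ** 2))
        rmse_after = np.sqrt(np.mean((resid.data[0] - neural) ** 2))
        assert rmse_after < 0.5 * rmse_before
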