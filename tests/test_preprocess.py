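"""Preprocessing: resampling, OD conversion, SQI pruning, artifact
correction and the modified Beer-Lambert law."""

import numpy as np
import pandas as pd
import pytest

from fnirsgait.core import Recording, default_montage
from fnirsgait.preprocess import (MbllCoefficients, compute_sqi, correct_spline,
                                  correct_wavelet, default_mbll_coefficients,
                                  dpf_general_equation, hb_to_od, intensity_to_od,
                                  od_to_hb, prune_channels, resample)
from conftest import make_events


def _rec(data, fs=50.0, unit="raw_intensity", channels=None, wavelengths=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    rows = pd.DataFrame({
        "channel": channels or [f"S{i + 1}-D{i + 1}" for i in range(n)],
        "wavelength_nm": wavelengths or [760.0] * n,
        "chromophore": ["n/a"] * n,
    })
    return Recording(data, fs, unit, rows)


class TestResample:
    def test_identity_at_same_rate(self, simple_recording):
        out = resample(simple_recording, 50.0)
        np.testing.assert_array_equal(out.data, simple_recording.data)

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(0, 60, 1 / 50)
        x = 1.0 + 0.2 * np.sin(2 * np.pi * 1.0 * t)
        out = resample(_rec(x), 60.0)
        assert out.fs_hz == pytest.approx(60.0)
        inner = out.data[0][120:-120]
        assert np.ptp(inner) == pytest.approx(0.4, rel=0.01)

    def test_constant_stays_constant(self):
        out = resample(_rec(np.full(500, 3.0)), 60.0)
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-2)

    def test_duration_preserved(self):
        out = resample(_rec(np.ones(500)), 60.0)
        assert abs(out.duration_s - 10.0) <= 1 / 50


class TestOpticalDensity:
    def test_constant_gives_zero(self):
        out = intensity_to_od(_rec(np.full(100, 2.0)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)
        assert out.unit == "optical_density"

    def test_definition(self):
        x = 0.3
        n = 100
        i = np.full(n, 10.0 ** (-x))
        i[::2] = 10.0 ** (x)  # mean of 10^x, 10^-x pattern
        out = intensity_to_od(_rec(i))
        mean = i.mean()
        np.testing.assert_allclose(out.data[0], -np.log10(i / mean), atol=1e-12)

    def test_nonpositive_errors_with_channel(self):
        i = np.ones(50)
        i[7] = -1.0
        with pytest.raises(ValueError, match="S1-D1"):
            intensity_to_od(_rec(i))


class TestSqi:
    def _standing(self):
        return make_events([dict(onset=0, duration=60, trial_type="stand",
                                 trigger="none", source="protocol")])

    def test_noise_channel_pruned_cardiac_retained(self):
        rng = np.random.default_rng(0)
        fs = 50.0
        t = np.arange(int(80 * fs)) / fs
        noise = 1.0 + 0.01 * rng.standard_normal(len(t))
        cardiac = np.power(10.0, -(0.005 * np.sin(2 * np.pi * 1.2 * t)
                                   + rng.normal(0, 0.0015, len(t))))
        rec = _rec(np.vstack([noise, cardiac]), fs=fs,
                   channels=["S1-D1", "S2-D2"])
        report = compute_sqi(rec, self._standing())
        assert report.pruned_channels() == {"S1-D1"}
        pruned = prune_channels(rec, report)
        np.testing.assert_array_equal(pruned.data, rec.data)  # data untouched
        assert "S1-D1" in pruned.pruned

    def test_all_clean_prunes_nothing(self, session_one_run):
        run = session_one_run.runs[0]
        report = compute_sqi(run.recording, run.protocol_events)
        assert report.pruned_channels() == frozenset()
        assert ((report.table["fraction_below_threshold"] >= 0)
                & (report.table["fraction_below_threshold"] <= 1)).all()

    def test_requires_standing_interval(self, simple_recording):
        from fnirsgait.core import EventTable
        with pytest.raises(ValueError, match="standing"):
            compute_sqi(simple_recording, EventTable())


class TestSpline:
    fs = 60.0

    def _base(self, seed=0, dur=120):
        rng = np.random.default_rng(seed)
        n = int(dur * self.fs)
        return (0.002 * np.sin(2 * np.pi * 0.1 * np.arange(n) / self.fs)
                + rng.normal(0, 0.0015, n))

    def test_artifact_free_is_identity(self):
        x = self._base()
        out = correct_spline(_rec(x, fs=self.fs, unit="optical_density"))
        np.testing.assert_array_equal(out.data[0], x)

    def test_spike_flagged_and_suppressed(self):
        base = self._base()
        x = base.copy()
        i0 = int(60 * self.fs)
        w = int(0.5 * self.fs)
        x[i0:i0 + w] += 0.1 * np.exp(-np.linspace(0, 4, w))
        out = correct_spline(_rec(x, fs=self.fs, unit="optical_density"))
        local = np.median(out.data[0][i0 - int(2 * self.fs):i0])
        resid_amp = np.abs(out.data[0][i0:i0 + w] - local).max()
        assert resid_amp <= 2 * np.std(base)
        # unflagged samples bit-identical
        changed = out.data[0] != x
        assert np.abs((out.data[0] - x)[~changed]).max(initial=0) < 1e-8

    def test_shift_reduced(self):
        base = self._base(seed=1)
        x = base.copy()
        j0, j1 = int(30 * self.fs), int(31.5 * self.fs)
        x[j0:j1] += 0.08
        out = correct_spline(_rec(x, fs=self.fs, unit="optical_density"))
        dev = np.abs(out.data[0][j0:j1] - base[j0:j1]).max()
        assert dev <= 0.1 * 0.08  # step size reduced by >= 90%

    def test_requires_od(self, simple_recording):
        with pytest.raises(ValueError):
            correct_spline(simple_recording)


class TestWavelet:
    def test_all_zero(self):
        out = correct_wavelet(_rec(np.zeros(4096), unit="optical_density"))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_gaussian_mass_retained(self):
        # with fences at Q1/Q3 -+ 0.8 IQR, a normal sample keeps
        # P(|z| < 1.7537) ~ 92% of detail coefficients
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096)
        import pywt
        coeffs = pywt.wavedec(x, "db2", mode="symmetric")
        kept = total = 0
        for cd in coeffs[1:]:
            if len(cd) < 32:
                continue
            q1, q3 = np.quantile(cd, [0.25, 0.75])
            lo, hi = q1 - 0.8 * (q3 - q1), q3 + 0.8 * (q3 - q1)
            kept += int(((cd >= lo) & (cd <= hi)).sum())
            total += len(cd)
        assert kept / total >= 0.90
        out = correct_wavelet(_rec(x, unit="optical_density"))
        ratio = out.data.var() / x.var()
        # variance loss equals the clipped-tail second moment (~38%)
        assert 0.5 < ratio < 0.8

    def test_spike_reduced(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 0.0015, 8192)
        x = base.copy()
        x[4000:4006] += 0.05
        out = correct_wavelet(_rec(x, unit="optical_density"))
        resid = np.abs(out.data[0][4000:4006] - base[4000:4006]).max()
        assert resid <= 0.2 * 0.05  # amplitude reduced >= 80%

    def test_length_preserved(self):
        for n in (1000, 1023, 4097):
            out = correct_wavelet(_rec(np.random.default_rng(0).normal(size=n),
                                       unit="optical_density"))
            assert out.n_samples == n


class TestMbll:
    def test_dpf_positive_and_wavelength_dependent(self):
        d760 = dpf_general_equation(760, 66)
        d850 = dpf_general_equation(850, 66)
        assert d760 > d850 > 0  # DPF decreases toward 850 nm

    def test_zero_od_gives_zero_hb(self, montage):
        ch = montage.channels[0]
        rec = _rec(np.zeros((2, 50)), unit="optical_density",
                   channels=[ch.id, ch.id], wavelengths=[760.0, 850.0])
        hb = od_to_hb(rec, montage, age_years=66)
        np.testing.assert_allclose(hb.data, 0.0, atol=1e-15)
        assert set(hb.rows["chromophore"]) == {"HbO", "HbR"}

    def test_round_trip_recovery(self, montage):
        """(dHbO, dHbR) = (1.0, -0.3) µM forward to OD and back to 1e-10."""
        ch = montage.channels[0]
        n = 100
        rows = pd.DataFrame({"channel": [ch.id, ch.id],
                             "wavelength_nm": [np.nan, np.nan],
                             "chromophore": ["HbO", "HbR"]})
        t = np.arange(n) / 10
        hb = Recording(np.vstack([1.0 * np.sin(t), -0.3 * np.sin(t)]),
                       10.0, "micromolar", rows)
        od = hb_to_od(hb, montage, age_years=66)
        back = od_to_hb(od, montage, age_years=66)
        np.testing.assert_allclose(back.data, hb.data, atol=1e-10)

    def test_linearity(self, montage):
        ch = montage.channels[0]
        rng = np.random.default_rng(0)
        def od_rec(data):
            rows = pd.DataFrame({"channel": [ch.id, ch.id],
                                 "wavelength_nm": [760.0, 850.0],
                                 "chromophore": ["n/a", "n/a"]})
            return Recording(data, 10.0, "optical_density", rows)
        x, y = rng.normal(size=(2, 50)), rng.normal(size=(2, 50))
        a, b = 2.0, -0.7
        lhs = od_to_hb(od_rec(a * x + b * y), montage, 66).data
        rhs = (a * od_to_hb(od_rec(x), montage, 66).data
               + b * od_to_hb(od_rec(y), montage, 66).data)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_singular_extinction_rejected(self):
        eps = {("HbO", 760.0): 1.0, ("HbR", 760.0): 2.0,
               ("HbO", 850.0): 2.0, ("HbR", 850.0): 4.0}
        with pytest.raises(ValueError, match="singular"):
            MbllCoefficients(extinction=eps).epsilon_matrix((760.0, 850.0))

    def test_default_wavelengths_accepted(self):
        m = default_mbll_coefficients().epsilon_matrix((760.0, 850.0))
        assert m.shape == (2, 2) and np.abs(np.linalg.det(m)) > 1.0
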