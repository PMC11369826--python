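"""Artifact preprocessing: resampling, channel-quality pruning, direct
motion-artifact correction and conversion to haemoglobin concentrations.

Stage order in the pipeline is resample -> prune -> optical density ->
spline correction -> wavelet correction -> MBLL; every stage is a pure
function of its input recording.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

from .core import EventTable, Montage, Recording


# ---------------------------------------------------------------- resampling


def resample(recording: Recording, target_fs: float = 60.0) -> Recording:
    """Polyphase resampling (anti-alias filtered); duration preserved
    within one sample."""
    if recording.unit not in ("raw_intensity", "optical_density"):
        raise ValueError("resample expects raw_intensity or optical_density data")
    if np.isclose(target_fs, recording.fs_hz):
        return recording.copy()
    frac = Fraction(target_fs / recording.fs_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(recording.data, up, down, axis=1, padtype="line")
    return recording.copy(data=data, fs_hz=recording.fs_hz * up / down)


# ---------------------------------------------------------------- signal quality


@dataclass
class SqiReport:
    """Per-channel signal quality during standing-still periods."""

    table: pd.DataFrame  # channel, fraction_below_threshold, mean_sqi, pruned
    threshold: float = 2.0

    def pruned_channels(self) -> frozenset:
        return frozenset(self.table.loc[self.table["pruned"], "channel"])


def _window_sqi(seg: np.ndarray, fs: float) -> float:
    """Map cardiac-band spectral prominence to the 1-4 quality scale.

    A clean optode shows a sharp cardiac peak (0.5-2.5 Hz) standing far
    above the broadband floor; a decoupled optode measuring noise or
    ambient light does not.
    """
    f, p = sps.periodogram(seg, fs=fs, detrend="linear", scaling="spectrum")
    band = (f >= 0.5) & (f <= 2.5)
    floor_band = (f >= 0.25) & (f <= min(5.0, f[-1]))
    if not band.any() or not floor_band.any():
        return 1.0
    floor = np.median(p[floor_band])
    if floor <= 0:
        return 1.0
    ratio = p[band].max() / floor
    return float(1.0 + 3.0 * np.clip((np.log10(ratio) - 0.5) / 1.0, 0.0, 1.0))


def compute_sqi(recording: Recording, standing_intervals: EventTable,
                window_s: float = 5.0, threshold: float = 2.0) -> SqiReport:
    """Windowed signal-quality index during standing, per channel.

    A channel's score in each window is the mean over its measurement rows
    (two wavelengths); ``fraction_below_threshold`` is the fraction of
    standing-time windows scoring below ``threshold``.
    """
    stands = standing_intervals.of_type("stand").df
    if len(stands) == 0:
        stands = standing_intervals.df
    if len(stands) == 0:
        raise ValueError("no standing intervals given; channel pruning needs explicit "
                         "standing-still periods")
    fs = recording.fs_hz
    data = recording.data
    if recording.unit == "raw_intensity":
        with np.errstate(divide="ignore", invalid="ignore"):
            ref = np.nanmean(data, axis=1, keepdims=True)
            data = -np.log10(np.clip(data, 1e-12, None) / np.clip(ref, 1e-12, None))
    w = int(round(window_s * fs))
    scores: dict[str, list[float]] = {}
    for _, ev in stands.iterrows():
        i0 = int(max(ev.onset - recording.time0_s, 0) * fs)
        i1 = int(min(ev.onset + ev.duration - recording.time0_s, recording.duration_s) * fs)
        for s in range(i0, max(i0, i1 - w) + 1, w):
            seg = data[:, s:s + w]
            if seg.shape[1] < w // 2:
                continue
            row_scores = [_window_sqi(seg[r], fs) for r in range(seg.shape[0])]
            per_row = pd.Series(row_scores, index=recording.rows["channel"].to_numpy())
            for ch, val in per_row.groupby(level=0).mean().items():
                scores.setdefault(ch, []).append(float(val))
    rows = []
    for ch in recording.rows["channel"].unique():
        vals = np.array(scores.get(ch, [1.0]))
        frac = float(np.mean(vals < threshold))
        rows.append(dict(channel=ch, fraction_below_threshold=frac,
                         mean_sqi=float(vals.mean()), pruned=frac > 0.5))
    return SqiReport(pd.DataFrame(rows), threshold=threshold)


def prune_channels(recording: Recording, report: SqiReport) -> Recording:
    """Record the prune mask; the data itself is untouched."""
    return recording.copy(pruned=recording.pruned | report.pruned_channels())


# ---------------------------------------------------------------- optical density


def intensity_to_od(recording: Recording) -> Recording:
    """OD(t) = -log10(I(t) / mean(I)) per measurement row."""
    if recording.unit != "raw_intensity":
        raise ValueError("intensity_to_od expects raw_intensity data")
    data = recording.data
    bad = np.flatnonzero((data <= 0).any(axis=1))
    if bad.size:
        labels = [recording.row_labels()[i] for i in bad[:5]]
        raise ValueError(f"non-positive intensity in rows {labels}")
    od = -np.log10(data / data.mean(axis=1, keepdims=True))
    return recording.copy(data=od, unit="optical_density")


# ---------------------------------------------------------------- spline correction


def _motion_flags(x: np.ndarray, fs: float, stdv_threshold: float,
                  amplitude_threshold: float, t_motion: float, t_mask: float) -> np.ndarray:
    """Flag samples whose local signal change exceeds the moving-std or
    amplitude criteria within ``t_motion`` windows, extended by ``t_mask``."""
    w = max(2, int(round(t_motion * fs)))
    local_range = maximum_filter1d(x, w) - minimum_filter1d(x, w)
    sd = np.std(np.diff(x))
    thresh = max(stdv_threshold * sd, 0.0)
    flags = (local_range > thresh) | (local_range > amplitude_threshold)
    ext = int(round(t_mask * fs))
    if ext > 0 and flags.any():
        flags = binary_dilation(flags, structure=np.ones(2 * ext + 1, dtype=bool))
    return flags


def _segments(flags: np.ndarray):
    edges = np.flatnonzero(np.diff(flags.astype(int)))
    starts = list(edges[flags[edges + 1]] + 1) if len(edges) else []
    if flags[0]:
        starts = [0] + starts
    out = []
    for s in starts:
        e = s
        while e < len(flags) and flags[e]:
            e += 1
        out.append((s, e))
    return out


def correct_spline(od: Recording, stdv_threshold: float = 65.0,
                   amplitude_threshold: float = 0.05, t_motion: float = 0.5,
                   t_mask: float = 1.0, smoothing_p: float = 0.99,
                   level_window_s: float = 2.0) -> Recording:
    """Spline-based correction of flagged motion segments.

    Within each flagged segment the signal is replaced by its residual
    about a closely-following smoothing spline (p = ``smoothing_p``) and
    re-levelled to the mean of the adjacent clean data; unflagged samples
    are returned bit-identical.
    """
    if od.unit != "optical_density":
        raise ValueError("correct_spline expects optical_density data")
    fs = od.fs_hz
    # cubic smoothing-spline trade-off on a unit sample grid; the /6 puts
    # the MATLAB-style p parameter on the roughness-penalty scale
    lam = (1.0 - smoothing_p) / (6.0 * smoothing_p)
    out = od.data.copy()
    wl = int(round(level_window_s * fs))
    for r in range(out.shape[0]):
        x = od.data[r]
        flags = _motion_flags(x, fs, stdv_threshold, amplitude_threshold, t_motion, t_mask)
        if not flags.any():
            continue
        for s, e in _segments(flags):
            seg = x[s:e]
            if len(seg) >= 8:
                xs = np.arange(len(seg), dtype=float)
                spl = make_smoothing_spline(xs, seg, lam=lam)
                resid = seg - spl(xs)
            else:
                resid = seg - seg.mean()
            if s > 0:
                level = x[max(0, s - wl):s].mean()
            elif e < len(x):
                level = x[e:e + wl].mean()
            else:
                level = seg.mean()
            out[r, s:e] = resid + level
    return od.copy(data=out)


# ---------------------------------------------------------------- wavelet correction


def correct_wavelet(od: Recording, iqr: float = 0.8, wavelet: str = "db2",
                    min_coeffs_per_level: int = 32) -> Recording:
    """Zero detail coefficients outside [Q1 - iqr*IQR, Q3 + iqr*IQR] per
    decomposition level and reconstruct (length-preserving).

    Levels with fewer than ``min_coeffs_per_level`` coefficients (the
    slow-drift scales) are left untouched: their quantiles cannot be
    estimated robustly and motion spikes carry no energy there.
    """
    if od.unit != "optical_density":
        raise ValueError("correct_wavelet expects optical_density data")
    out = np.empty_like(od.data)
    n = od.n_samples
    for r in range(od.data.shape[0]):
        x = od.data[r]
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric")
        cleaned = [coeffs[0]]
        for cd in coeffs[1:]:
            if len(cd) >= min_coeffs_per_level:
                q1, q3 = np.quantile(cd, [0.25, 0.75])
                spread = q3 - q1
                lo, hi = q1 - iqr * spread, q3 + iqr * spread
                cd = np.where((cd < lo) | (cd > hi), 0.0, cd)
            cleaned.append(cd)
        rec = pywt.waverec(cleaned, wavelet, mode="symmetric")
        out[r] = rec[:n]
    return od.copy(data=out)


# ---------------------------------------------------------------- MBLL


def dpf_general_equation(wavelength_nm: float, age_years: float) -> float:
    """Differential pathlength factor from the published general equation
    for the adult head as a function of age and wavelength."""
    a = float(age_years)
    wl = float(wavelength_nm)
    return (223.3 + 0.05624 * a ** 0.8493
            - 5.723e-7 * wl ** 3 + 0.001245 * wl ** 2 - 0.9025 * wl)


def _load_extinction_table() -> dict:
    ref = importlib.resources.files("fnirsgait").joinpath("data/extinction_coefficients.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return {(r.chromophore, float(r.wavelength_nm)): float(r.epsilon_per_mM_cm)
            for r in df.itertuples()}


@dataclass
class MbllCoefficients:
    """Extinction coefficients and DPF model for the modified Beer-Lambert law."""

    extinction: dict  # {(chromophore, wavelength_nm): 1/(mM*cm)}
    dpf_table: dict = field(default_factory=dict)  # optional {(wl, age): dpf} override

    def dpf(self, wavelength_nm: float, age_years: float) -> float:
        key = (float(wavelength_nm), float(age_years))
        if key in self.dpf_table:
            return self.dpf_table[key]
        val = dpf_general_equation(wavelength_nm, age_years)
        if val <= 0:
            raise ValueError("DPF must be positive")
        return val

    def epsilon_matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 matrix: rows wavelengths, columns (HbO, HbR)."""
        try:
            m = np.array([[self.extinction[("HbO", wl)], self.extinction[("HbR", wl)]]
                          for wl in wavelengths])
        except KeyError as e:
            raise ValueError(f"no extinction coefficient for {e}") from e
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("extinction coefficient matrix is singular")
        return m


def default_mbll_coefficients() -> MbllCoefficients:
    return MbllCoefficients(extinction=_load_extinction_table())


def od_to_hb(od: Recording, montage: Montage, age_years: float,
             coeffs: MbllCoefficients | None = None) -> Recording:
    """Solve the modified Beer-Lambert law per channel.

    dOD(lambda) = d * DPF(lambda, age) * [eps_HbO dHbO + eps_HbR dHbR]
    with concentrations in mM; the output carries one HbO and one HbR row
    per channel in micromolar.
    """
    if od.unit != "optical_density":
        raise ValueError("od_to_hb expects optical_density data")
    coeffs = coeffs or default_mbll_coefficients()
    wls = montage.wavelengths_nm
    eps = coeffs.epsilon_matrix(wls)
    out_rows = []
    out_data = []
    for ch in od.rows["channel"].unique():
        idx = {}
        for i in np.flatnonzero((od.rows["channel"] == ch).to_numpy()):
            idx[float(od.rows["wavelength_nm"].iloc[i])] = i
        if set(idx) != set(float(w) for w in wls):
            raise ValueError(f"channel {ch} lacks both wavelength rows")
        c = montage.channel(ch)
        d_cm = c.interoptode_distance_mm / 10.0
        # effective pathlength per wavelength
        L = np.array([d_cm * coeffs.dpf(wl, age_years) for wl in wls])
        A = eps * L[:, None]  # 2x2
        od_mat = np.vstack([od.data[idx[float(wl)]] for wl in wls])
        hb_mM = np.linalg.solve(A, od_mat)
        for k, chromo in enumerate(("HbO", "HbR")):
            out_rows.append(dict(channel=ch, wavelength_nm=np.nan, chromophore=chromo))
            out_data.append(hb_mM[k] * 1000.0)  # -> µM
    return od.copy(data=np.vstack(out_data), unit="micromolar",
                   rows=pd.DataFrame(out_rows))


def hb_to_od(hb: Recording, montage: Montage, age_years: float,
             coeffs: MbllCoefficients | None = None) -> Recording:
    """Forward MBLL (µM concentrations -> optical density); the inverse of
    :func:`od_to_hb`, used by the generator and round-trip checks."""
    if hb.unit != "micromolar":
        raise ValueError("hb_to_od expects micromolar data")
    coeffs = coeffs or default_mbll_coefficients()
    wls = montage.wavelengths_nm
    eps = coeffs.epsilon_matrix(wls)
    out_rows = []
    out_data = []
    for ch in hb.rows["channel"].unique():
        sel = {r.chromophore: i for i, r in hb.rows.iterrows() if r.channel == ch}
        if set(sel) != {"HbO", "HbR"}:
            raise ValueError(f"channel {ch} lacks HbO/HbR rows")
        c = montage.channel(ch)
        d_cm = c.interoptode_distance_mm / 10.0
        conc = np.vstack([hb.data[sel["HbO"]], hb.data[sel["HbR"]]]) / 1000.0  # mM
        for k, wl in enumerate(wls):
            L = d_cm * coeffs.dpf(wl, age_years)
            out_rows.append(dict(channel=ch, wavelength_nm=float(wl), chromophore="n/a"))
            out_data.append(L * (eps[k] @ conc))
    return hb.copy(data=np.vstack(out_data), unit="optical_density",
                   rows=pd.DataFrame(out_rows))
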