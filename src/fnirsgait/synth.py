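"""Synthetic ambulatory-fNIRS sessions with known ground truth.

Emulates the corridor gait task: runs of ~6.5 min starting with 60 s of
quiet standing, ~20 s walking legs between a doorway and turning squares,
instructed 30 s stops every 2.5 corridor lengths, and freezing episodes
attached to their typical triggers (turns, doorways, destination,
starts, straight walking).  Each session comprises

* raw dual-wavelength intensities (50 Hz) built by a forward model:
  canonical double-gamma haemodynamic responses per ROI and condition,
  a low-rank systemic confound shared between long and short channels,
  a head-pitch-coupled indirect movement artifact, direct spike/shift
  artifacts in optical density, and white measurement noise;
* 60 Hz head/body kinematics consistent with the event schedule;
* two raters' freeze annotations (rater B is a jittered copy of rater A
  within the merge tolerance, with occasional misses);
* a :class:`GroundTruth` record of every constant used.

Short channels receive the systemic and scalp components but no neural
term, so confound regression can be validated against construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventTable, Kinematics, Montage, Recording, ROIS, default_montage
from .preprocess import MbllCoefficients, default_mbll_coefficients

CONDITIONS = ("turn", "doorway", "stop", "start", "freeze")

_TYPE_TO_CONDITION = {
    "turn_left": "turn",
    "turn_right": "turn",
    "doorway": "doorway",
    "stop": "stop",
    "start": "start",
    "freeze": "freeze",
}


def double_gamma_hrf(t: np.ndarray, peak_delay_s: float = 6.0,
                     undershoot_delay_s: float = 16.0, ratio: float = 1 / 6) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalised to 1."""
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, a=peak_delay_s + 1.0, scale=1.0) \
        - ratio * gamma.pdf(t, a=undershoot_delay_s + 1.0, scale=1.0)
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class ProtocolSpec:
    """Timing of the gait task (defaults follow the study protocol)."""

    n_runs: int = 4
    run_length_s: float = 390.0
    initial_stand_s: float = 60.0
    walk_leg_s: float = 20.0
    stop_duration_s: float = 30.0
    legs_per_stop: int = 5         # 2.5 corridor lengths
    turn_duration_s: float = 2.5
    doorway_duration_s: float = 1.0
    start_duration_s: float = 2.0
    walking_speed_ms: float = 1.05
    freeze_rates: dict = field(default_factory=lambda: {
        "turn": 0.33, "doorway": 0.17, "destination": 0.30, "start": 0.08})
    walking_freeze_rate_per_s: float = 0.001
    freeze_median_s: float = 3.8
    freeze_sigma_log: float = 0.6
    freeze_max_s: float = 20.0

    def __post_init__(self) -> None:
        used = self.initial_stand_s + self.walk_leg_s
        if used > self.run_length_s:
            raise ValueError("events do not fit within run length")


def default_roi_amplitudes() -> dict:
    """True peak ΔHbO responses (µM) per (condition, ROI).

    Signs follow the qualitative pattern of ambulatory stopping/freezing
    studies: premotor/prefrontal activation during stops and turns, M1
    deactivation when halting, and a prefrontal *decrease* during freezing.
    """
    return {
        ("stop", "M1"): -0.20, ("stop", "PMC"): 0.15, ("stop", "SMA"): 0.30,
        ("stop", "PFC"): 0.30, ("stop", "PPC"): 0.05,
        ("turn", "M1"): 0.10, ("turn", "PMC"): 0.25, ("turn", "SMA"): 0.25,
        ("turn", "PFC"): 0.20, ("turn", "PPC"): 0.10,
        ("doorway", "M1"): 0.05, ("doorway", "PMC"): 0.20, ("doorway", "SMA"): 0.15,
        ("doorway", "PFC"): 0.25, ("doorway", "PPC"): 0.10,
        ("start", "M1"): -0.15, ("start", "PMC"): -0.15, ("start", "SMA"): 0.05,
        ("start", "PFC"): 0.05, ("start", "PPC"): 0.00,
        ("freeze", "M1"): 0.00, ("freeze", "PMC"): 0.10, ("freeze", "SMA"): 0.20,
        ("freeze", "PFC"): -0.30, ("freeze", "PPC"): 0.00,
    }


@dataclass
class GroundTruth:
    """Everything the generator knows; recovery tests read from here."""

    roi_amplitudes: dict = field(default_factory=default_roi_amplitudes)
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_ratio: float = 1 / 6
    systemic_rank: int = 8
    systemic_scale_uM: float = 1.5       # scale of the scalp systemic signal per channel
    long_systemic_share: float = 0.6     # fraction of the scalp signal seen by long channels
    hbr_ratio: float = -1 / 3
    kinematic_gain_uM_per_deg: float = 0.02
    noise_od_sd: float = 1.5e-3
    spike_prob: float = 0.10             # per turn/freeze event
    shift_prob: float = 0.05
    spike_amp_od: tuple = (0.05, 0.15)
    shift_amp_od: tuple = (0.02, 0.05)
    freeze_surge_uM: float = 0.0         # heart-rate-like HbO surge at freeze onsets
    seed: int = 0
    # relative amplitude of each systemic component class (slow
    # blood-pressure drifts dominate; cardiac pulsation is small in OD
    # terms but is what the signal-quality index keys on)
    component_scales: dict = field(default_factory=lambda: {
        "drift": 1.0, "drift2": 0.7, "mayer": 0.5,
        "respiration": 0.3, "cardiac": 0.25})
    # filled in by generate_session:
    loadings: np.ndarray | None = None
    component_freqs: dict = field(default_factory=lambda: {
        "mayer": 0.1, "respiration": 0.25, "cardiac": 1.2})
    channel_gains: np.ndarray | None = None
    artifact_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.systemic_rank > 8:
            raise ValueError("systemic rank must be <= 8")
        for key, amp in self.roi_amplitudes.items():
            if not np.isfinite(amp):
                raise ValueError(f"non-finite amplitude for {key}")


# ------------------------------------------------------------- protocol


def generate_protocol(spec: ProtocolSpec, seed: int, run_index: int = 0,
                      freezer: bool = True, freeze_scale: float = 1.0) -> EventTable:
    """Lay out one run's event schedule; deterministic given (seed, run_index).

    Turn directions alternate between corridor ends and switch after every
    instructed stop; freezes are drawn at their trigger-specific rates with
    log-normal durations (median ``freeze_median_s``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 77, run_index]))
    rows: list[dict] = []

    def add(onset, duration, ttype, trigger="none", source="protocol"):
        rows.append(dict(onset=float(onset), duration=float(duration),
                         trial_type=ttype, trigger=trigger, source=source))

    def freeze_duration():
        d = float(np.exp(np.log(spec.freeze_median_s)
                         + spec.freeze_sigma_log * rng.standard_normal()))
        return min(d, spec.freeze_max_s)

    def maybe_freeze(trigger, onset):
        if not freezer:
            return
        rate = spec.freeze_rates.get(trigger, 0.0) * freeze_scale
        if rng.random() < min(rate, 1.0):
            add(max(onset, 0.0), freeze_duration(), "freeze", trigger=trigger)

    add(0.0, spec.initial_stand_s, "stand")
    t = spec.initial_stand_s
    add(t, spec.start_duration_s, "start")
    maybe_freeze("start", t)

    # landmark sequence: square A -> door -> square B -> door -> A ...
    at_square = True  # starting at a square; first leg ends at the door
    turn_dir = 1 if run_index % 2 == 0 else -1
    legs_done = 0
    while True:
        leg_end = t + spec.walk_leg_s
        if leg_end + spec.turn_duration_s > spec.run_length_s:
            break
        # walking freeze somewhere inside the leg
        if freezer and rng.random() < min(
                spec.walking_freeze_rate_per_s * spec.walk_leg_s * freeze_scale, 1.0):
            add(t + rng.uniform(2.0, spec.walk_leg_s - 2.0), freeze_duration(),
                "freeze", trigger="walking")
        t = leg_end
        arrived_at_square = not at_square
        at_square = arrived_at_square
        legs_done += 1
        stopping = legs_done % spec.legs_per_stop == 0
        if stopping:
            if t + spec.stop_duration_s + spec.start_duration_s > spec.run_length_s:
                break
            maybe_freeze("destination", t - 1.0)
            add(t, spec.stop_duration_s, "stop", trigger="destination")
            t += spec.stop_duration_s
            add(t, spec.start_duration_s, "start")
            maybe_freeze("start", t)
            turn_dir *= -1  # direction switch after each instructed stop
        elif arrived_at_square:
            ttype = "turn_left" if turn_dir > 0 else "turn_right"
            add(t, spec.turn_duration_s, ttype)
            maybe_freeze("turn", t)
            t += spec.turn_duration_s
            turn_dir *= -1  # alternate direction between squares
        else:
            add(t, spec.doorway_duration_s, "doorway")
            maybe_freeze("doorway", t - 0.3)
    return EventTable(pd.DataFrame(rows))


def rater_annotations(true_freezes: EventTable, seed: int,
                      miss_prob_b: float = 0.05) -> tuple[EventTable, EventTable]:
    """Two raters' freeze annotations derived from the true episodes.

    Rater A jitters boundaries slightly; rater B is rater A jittered by at
    most the merge tolerance (2 s) and occasionally misses an episode, so
    that merging and agreement metrics are exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 911]))
    rows_a, rows_b = [], []
    for _, ev in true_freezes.df.iterrows():
        on_a = max(0.0, ev.onset + rng.normal(0, 0.2))
        dur_a = max(0.4, ev.duration + rng.normal(0, 0.2))
        rows_a.append(dict(onset=on_a, duration=dur_a, trial_type="freeze",
                           trigger=ev.trigger, source="rater_A"))
        if rng.random() < miss_prob_b:
            continue
        jit = float(np.clip(rng.normal(0, 0.5), -1.5, 1.5))
        rows_b.append(dict(onset=max(0.0, on_a + jit),
                           duration=max(0.4, dur_a + rng.normal(0, 0.3)),
                           trial_type="freeze", trigger=ev.trigger, source="rater_B"))
    return (EventTable(pd.DataFrame(rows_a, columns=true_freezes.df.columns)),
            EventTable(pd.DataFrame(rows_b, columns=true_freezes.df.columns)))


# ------------------------------------------------------------- kinematics


def _smooth(x: np.ndarray, fs: float, width_s: float) -> np.ndarray:
    n = max(3, int(round(width_s * fs)) | 1)
    w = np.hanning(n)
    w /= w.sum()
    return np.convolve(np.pad(x, (n // 2, n // 2), mode="edge"), w, mode="valid")[: len(x)]


def kinematics_from_events(events: EventTable, spec: ProtocolSpec, seed: int,
                           speed_ms: float | None = None, fs: float = 60.0,
                           run_length_s: float | None = None,
                           run_id: str = "run-01") -> Kinematics:
    """Build a 60 Hz kinematics stream consistent with the event schedule.

    Walking position advances along the corridor only during "moving"
    samples (not standing, stopped, frozen or mid-turn); turns rotate yaw by
    180 deg; the head pitches down around turns, stops, doorways and
    freezes (the behaviour the motion regressors are there to capture).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 13]))
    speed = speed_ms if speed_ms is not None else spec.walking_speed_ms
    T = run_length_s if run_length_s is not None else spec.run_length_s
    n = int(round(T * fs))
    t = np.arange(n) / fs

    halted = np.zeros(n, dtype=bool)   # standing / stopped / frozen
    turning = np.zeros(n, dtype=bool)
    pitch_drive = np.zeros(n)
    df = events.df
    for _, ev in df.iterrows():
        i0, i1 = int(ev.onset * fs), int(min((ev.onset + ev.duration) * fs, n))
        if ev.trial_type in ("stand", "stop", "freeze"):
            halted[i0:i1] = True
        if ev.trial_type in ("turn_left", "turn_right"):
            turning[i0:i1] = True
        if ev.trial_type in ("turn_left", "turn_right", "stop", "freeze", "doorway"):
            j1 = int(min((ev.onset + max(ev.duration, 2.0)) * fs, n))
            pitch_drive[i0:j1] = np.maximum(pitch_drive[i0:j1], 1.0)

    moving = ~(halted | turning)
    leg_dist = spec.walk_leg_s * speed
    corridor = 2.0 * leg_dist

    # replay the schedule's state machine: landmark waypoints (time, x) and
    # yaw rotations; walking direction flips at turns and at square stops
    # (the protocol's mid-stop turn-around)
    waypoints: list[tuple[float, float]] = []
    rotations: list[tuple[float, float, float, bool]] = []  # t0, dur, delta, during_halt
    p, dirn = 0.0, 1.0
    first_start = df[df["trial_type"] == "start"]
    t_walk0 = float(first_start["onset"].iloc[0]) if len(first_start) else 0.0
    waypoints.append((t_walk0, p))
    for _, ev in df.iterrows():
        if ev.trial_type == "doorway":
            p += dirn * leg_dist
            waypoints.append((float(ev.onset), p))
        elif ev.trial_type in ("turn_left", "turn_right"):
            p += dirn * leg_dist
            waypoints.append((float(ev.onset), p))
            sgn = 1.0 if ev.trial_type == "turn_left" else -1.0
            rotations.append((float(ev.onset), float(ev.duration), sgn * 180.0, False))
            dirn *= -1.0
        elif ev.trial_type == "stop":
            p += dirn * leg_dist
            waypoints.append((float(ev.onset), p))
            at_square = min(abs(p), abs(p - corridor)) < 0.5
            if at_square:
                rotations.append((float(ev.onset + ev.duration / 2.0),
                                  spec.turn_duration_s, 180.0, True))
                dirn *= -1.0

    # position: within each leg, distance accrues over moving samples so
    # that landmark arrivals match the schedule even when a freeze pauses
    # forward progression
    x = np.zeros(n)
    mv = moving.astype(float)
    for (t_a, p_a), (t_b, p_b) in zip(waypoints[:-1], waypoints[1:]):
        i_a, i_b = int(t_a * fs), min(int(t_b * fs), n)
        if i_b <= i_a:
            continue
        frac = np.cumsum(mv[i_a:i_b])
        total = frac[-1] if frac[-1] > 0 else 1.0
        x[i_a:i_b] = p_a + (p_b - p_a) * frac / total
        x[i_b:] = p_b
    if waypoints:
        t_last, p_last = waypoints[-1]
        i_last = int(t_last * fs)
        if i_last < n:  # final partial leg: extrapolate at cruise speed
            x[i_last:] = p_last + dirn * speed / fs * np.cumsum(mv[i_last:])

    yaw = np.zeros(n)
    for t0, dur, delta, during_halt in rotations:
        i0 = int(t0 * fs)
        need = max(1, int(round(dur * fs)))
        count, i = 0, i0
        while count < need and i < n:
            if during_halt or not halted[i]:
                yaw[i:] += delta / need
                count += 1
            i += 1

    x = _smooth(x, fs, 0.3)
    vel = np.abs(np.gradient(x) * fs)
    # the body keeps moving while rotating in the square; the position
    # trace is stationary there but gait does not cease
    vel = np.where(turning & ~halted, np.maximum(vel, 0.45 * speed), vel)
    vel = _smooth(vel, fs, 0.3) + rng.normal(0, 0.01, n)

    pitch = -5.0 - 10.0 * _smooth(pitch_drive, fs, 1.5) + rng.normal(0, 0.3, n)
    yaw_s = _smooth(yaw, fs, 0.3)
    yaw_rel = rng.normal(0, 0.5, n)
    roll = rng.normal(0, 0.5, n)

    stride = np.sin(2 * np.pi * 1.8 * t + rng.uniform(0, 2 * np.pi))
    gait_amp = _smooth(vel, fs, 1.0) / max(speed, 0.1)
    acc = np.vstack([
        0.3 * stride * gait_amp + rng.normal(0, 0.05, n),
        0.2 * np.sin(2 * np.pi * 0.9 * t) * gait_amp + rng.normal(0, 0.05, n),
        0.5 * stride * gait_amp + rng.normal(0, 0.05, n),
    ])
    yaw_rate = np.gradient(yaw_s) * fs
    angacc = np.vstack([
        np.deg2rad(np.gradient(yaw_rate) * fs) + rng.normal(0, 0.05, n),
        rng.normal(0, 0.05, n),
        rng.normal(0, 0.05, n),
    ])
    series = {
        "head_acceleration": acc,
        "head_angular_acceleration": angacc,
        "head_neck_orientation": np.vstack([yaw_rel, pitch, roll]),
        "body_velocity": vel[None, :],
        "body_position": np.vstack([x, rng.normal(0, 0.02, n)]),
    }
    return Kinematics(fs_hz=fs, series=series, run_id=run_id)


# ------------------------------------------------------------- fNIRS forward model


def _normalized_response(duration_s: float, hrf_kernel: np.ndarray, fs: float) -> np.ndarray:
    box = np.ones(max(1, int(round(duration_s * fs))))
    r = np.convolve(box, hrf_kernel)
    m = np.abs(r).max()
    return r / m if m > 0 else r


def neural_drive(n: int, fs: float, events: EventTable, amplitudes: dict,
                 truth: GroundTruth) -> dict:
    """Per-ROI noiseless ΔHbO (µM): sum of event responses.

    Each event contributes its (condition, ROI) amplitude times a
    peak-normalised HRF-convolved boxcar of the event's duration.
    """
    tk = np.arange(0, 32.0, 1 / fs)
    kernel = double_gamma_hrf(tk, truth.hrf_peak_delay_s,
                              truth.hrf_undershoot_delay_s, truth.hrf_ratio)
    cache: dict[float, np.ndarray] = {}
    out = {roi: np.zeros(n) for roi in ROIS}
    for _, ev in events.df.iterrows():
        cond = _TYPE_TO_CONDITION.get(ev.trial_type)
        if cond is None:
            continue
        dur = round(min(max(ev.duration, 0.5), 30.0), 1)
        if dur not in cache:
            cache[dur] = _normalized_response(dur, kernel, fs)
        resp = cache[dur]
        i0 = int(round(ev.onset * fs))
        if i0 >= n:
            continue
        seg = resp[: n - i0]
        for roi in ROIS:
            amp = amplitudes.get((cond, roi), 0.0)
            if amp:
                out[roi][i0:i0 + len(seg)] += amp * seg
    return out


def systemic_components(n: int, fs: float, rng: np.random.Generator,
                        truth: GroundTruth) -> np.ndarray:
    """Rank-``systemic_rank`` component matrix (k x n), unit-variance rows.

    Two slow drift components plus quadrature pairs at the Mayer-wave,
    respiratory and cardiac frequencies with slowly wandering phase.
    """
    t = np.arange(n) / fs
    comps = []
    scales = []
    for key in ("drift", "drift2"):  # slow blood-pressure drifts
        w = np.cumsum(rng.standard_normal(n))
        comps.append(_smooth(w, fs, 20.0))
        scales.append(truth.component_scales[key])
    for name in ("mayer", "respiration", "cardiac"):
        f = truth.component_freqs[name]
        wander = _smooth(np.cumsum(rng.standard_normal(n)) / fs, fs, 10.0) * 0.2
        phase = 2 * np.pi * f * t + wander
        comps.append(np.sin(phase))
        comps.append(np.cos(phase))
        scales.extend([truth.component_scales[name]] * 2)
    C = np.vstack(comps)[: truth.systemic_rank]
    sd = C.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return C / sd * np.asarray(scales)[: truth.systemic_rank, None]


def _surge_timecourse(n: int, fs: float, freeze_onsets: np.ndarray) -> np.ndarray:
    """Heart-rate-like transient locked to freeze onsets (peaks ~3 s after)."""
    from scipy.stats import gamma

    tk = np.arange(0, 15.0, 1 / fs)
    bump = gamma.pdf(tk, a=3.0, scale=1.2)
    bump /= bump.max()
    s = np.zeros(n)
    for on in freeze_onsets:
        i0 = int(round(on * fs))
        if i0 >= n:
            continue
        seg = bump[: n - i0]
        s[i0:i0 + len(seg)] += seg
    return s


@dataclass
class RunData:
    run_id: str
    recording: Recording          # raw intensity, 50 Hz
    kinematics: Kinematics        # 60 Hz
    protocol_events: EventTable   # full schedule incl. true freezes
    events_rater_a: EventTable
    events_rater_b: EventTable
    clean_neural_hbo: np.ndarray | None = None  # long channels x samples, µM, 50 Hz


@dataclass
class Session:
    participant: str
    group: str                    # "PD" | "HC"
    age: float
    montage: Montage
    runs: list
    truth: GroundTruth
    meta: dict = field(default_factory=dict)


def generate_session(spec: ProtocolSpec, truth: GroundTruth, participant_meta: dict,
                     seed: int, fs_nirs: float = 50.0, store_clean: bool = True,
                     coeffs: MbllCoefficients | None = None) -> Session:
    """Generate one participant's full session (all runs) with ground truth."""
    truth = dataclasses.replace(truth)
    truth.seed = int(seed) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 5]))
    montage = default_montage()
    group = participant_meta.get("group", "PD")
    age = float(participant_meta.get("age", 66.0))
    pid = participant_meta.get("participant", "sub-01")
    freezer = bool(participant_meta.get("freezer", group == "PD"))
    speed = float(participant_meta.get("speed_ms", spec.walking_speed_ms))
    freeze_scale = float(participant_meta.get("freeze_scale", 1.0))
    coeffs = coeffs or default_mbll_coefficients()

    amps = dict(truth.roi_amplitudes)
    for key, delta in participant_meta.get("amp_delta", {}).items():
        amps[key] = amps.get(key, 0.0) + delta

    chans = montage.channels
    n_ch = len(chans)
    long_idx = [i for i, c in enumerate(chans) if c.kind == "long"]
    k = truth.systemic_rank
    W = rng.standard_normal((n_ch, k)) * truth.systemic_scale_uM / np.sqrt(k)
    cardiac_col = min(6, k - 1)  # sin component of the cardiac pair
    W[:, cardiac_col] = np.abs(W[:, cardiac_col])  # pulse raises HbO everywhere
    truth.loadings = W
    gains = 1.0 + 0.1 * rng.standard_normal(len(long_idx))
    truth.channel_gains = gains
    kin_gain = truth.kinematic_gain_uM_per_deg * (1.0 + 0.3 * rng.standard_normal(n_ch))

    eps = coeffs.extinction  # {(chromo, wl): 1/(mM cm)}
    wls = montage.wavelengths_nm

    runs = []
    for r in range(spec.n_runs):
        run_id = f"run-{r + 1:02d}"
        events = generate_protocol(spec, truth.seed + 1000 * r, run_index=r,
                                   freezer=freezer, freeze_scale=freeze_scale)
        kin = kinematics_from_events(events, spec, truth.seed + 1000 * r + 1,
                                     speed_ms=speed, run_id=run_id)
        n = int(round(spec.run_length_s * fs_nirs))

        drive = neural_drive(n, fs_nirs, events, amps, truth)
        C = systemic_components(n, fs_nirs, rng, truth)
        freezes = events.of_type("freeze").df["onset"].to_numpy()
        surge = (_surge_timecourse(n, fs_nirs, freezes) * truth.freeze_surge_uM
                 if truth.freeze_surge_uM else None)

        # head pitch resampled onto the fNIRS clock (indirect artifact source)
        pitch60 = kin.series["head_neck_orientation"][1]
        t50 = np.arange(n) / fs_nirs
        pitch50 = np.interp(t50, kin.times(), pitch60)
        pitch50 = pitch50 - pitch50.mean()

        hbo = np.zeros((n_ch, n))
        sysmat = W @ C  # channels x samples, µM
        if surge is not None:
            wsurge = W[:, cardiac_col] / max(W[:, cardiac_col].mean(), 1e-9)
            sysmat = sysmat + wsurge[:, None] * surge[None, :]
        clean = np.zeros((len(long_idx), n))
        for j, i in enumerate(long_idx):
            neural = gains[j] * drive[chans[i].roi]
            clean[j] = neural
            hbo[i] = neural + truth.long_systemic_share * sysmat[i] + kin_gain[i] * pitch50
        for i, c in enumerate(chans):
            if c.kind == "short":
                hbo[i] = sysmat[i] + kin_gain[i] * 0.5 * pitch50
        hbr = truth.hbr_ratio * hbo

        # forward MBLL to optical density, then direct artifacts + noise
        data = np.empty((2 * n_ch, n))
        rows = []
        arts = []
        for i, c in enumerate(chans):
            d_cm = c.interoptode_distance_mm / 10.0
            for w, wl in enumerate(wls):
                od = d_cm * coeffs.dpf(wl, age) * (
                    eps[("HbO", wl)] * hbo[i] / 1000.0 + eps[("HbR", wl)] * hbr[i] / 1000.0
                )
                data[2 * i + w] = od
                rows.append(dict(channel=c.id, wavelength_nm=wl, chromophore="n/a"))
        motion_events = events.of_type("turn_left", "turn_right", "freeze").df
        for _, ev in motion_events.iterrows():
            if rng.random() < truth.spike_prob:
                amp = rng.uniform(*truth.spike_amp_od) * rng.choice([-1, 1])
                dur = rng.uniform(0.3, 1.0)
                i0 = int(ev.onset * fs_nirs)
                m = int(dur * fs_nirs)
                shape = amp * np.exp(-np.linspace(0, 4, m))
                hit = rng.random(n_ch) < 0.2
                for i in np.flatnonzero(hit):
                    for w in range(2):
                        seg = shape[: n - i0]
                        data[2 * i + w, i0:i0 + len(seg)] += seg * rng.uniform(0.8, 1.2)
                arts.append((run_id, float(ev.onset), "spike"))
            if rng.random() < truth.shift_prob:
                amp = rng.uniform(*truth.shift_amp_od) * rng.choice([-1, 1])
                i0 = int(ev.onset * fs_nirs)
                i1 = min(n, i0 + int(rng.uniform(10, 30) * fs_nirs))
                hit = rng.random(n_ch) < 0.2
                for i in np.flatnonzero(hit):
                    for w in range(2):
                        data[2 * i + w, i0:i1] += amp * rng.uniform(0.8, 1.2)
                arts.append((run_id, float(ev.onset), "shift"))
        truth.artifact_times.setdefault(run_id, []).extend(arts)
        data += rng.normal(0, truth.noise_od_sd, data.shape)

        i0s = rng.uniform(0.5, 2.0, (2 * n_ch, 1))
        intensity = i0s * np.power(10.0, -data)
        rec = Recording(data=intensity, fs_hz=fs_nirs, unit="raw_intensity",
                        rows=pd.DataFrame(rows), run_id=run_id)
        ra, rb = rater_annotations(events.of_type("freeze"), truth.seed + 1000 * r + 2)
        runs.append(RunData(run_id=run_id, recording=rec, kinematics=kin,
                            protocol_events=events, events_rater_a=ra, events_rater_b=rb,
                            clean_neural_hbo=clean if store_clean else None))
    return Session(participant=pid, group=group, age=age, montage=montage,
                   runs=runs, truth=truth, meta=dict(participant_meta))


# ------------------------------------------------------------- cohort


@dataclass
class CohortSpec:
    """A small synthetic cohort; group-level differences are generator truth."""

    n_pd: int = 4
    n_hc: int = 4
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    truth: GroundTruth = field(default_factory=GroundTruth)
    pd_speed_ms: float = 0.95
    hc_speed_ms: float = 1.09
    speed_sd: float = 0.08
    age_mean: float = 66.0
    age_sd: float = 9.0
    # PD deviations from the shared amplitude table (condition, ROI) -> µM
    pd_amp_delta: dict = field(default_factory=lambda: {
        ("stop", "SMA"): 0.20, ("stop", "PFC"): 0.20,
        ("turn", "PMC"): 0.15, ("turn", "SMA"): 0.12})
    severity_pfc_doorway_slope: float = 0.0  # µM per sd of latent freeze severity


def cohort_metadata(cohort: CohortSpec, seed: int) -> list[dict]:
    """Participant metadata drawn once per cohort (deterministic given seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 21]))
    metas = []
    idx = 1
    for group, ngrp in (("PD", cohort.n_pd), ("HC", cohort.n_hc)):
        for _ in range(ngrp):
            severity = float(rng.standard_normal()) if group == "PD" else 0.0
            meta = {
                "participant": f"sub-{idx:02d}",
                "group": group,
                "age": float(rng.normal(cohort.age_mean, cohort.age_sd)),
                "freezer": group == "PD",
                "speed_ms": float(rng.normal(
                    cohort.pd_speed_ms if group == "PD" else cohort.hc_speed_ms,
                    cohort.speed_sd)),
                "updrs": float(rng.normal(44.0, 10.0)) if group == "PD" else 0.0,
                "severity": severity,
                "freeze_scale": float(np.exp(0.4 * severity)) if group == "PD" else 0.0,
                "amp_delta": {},
            }
            if group == "PD":
                meta["amp_delta"] = dict(cohort.pd_amp_delta)
                if cohort.severity_pfc_doorway_slope:
                    meta["amp_delta"][("doorway", "PFC")] = (
                        meta["amp_delta"].get(("doorway", "PFC"), 0.0)
                        + cohort.severity_pfc_doorway_slope * severity)
            metas.append(meta)
            idx += 1
    return metas


def generate_cohort(cohort: CohortSpec, seed: int, store_clean: bool = False):
    """Yield one :class:`Session` per participant."""
    for i, meta in enumerate(cohort_metadata(cohort, seed)):
        yield generate_session(cohort.protocol, cohort.truth, meta,
                               seed=(int(seed) + 7919 * (i + 1)) % (2**31),
                               store_clean=store_clean)
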