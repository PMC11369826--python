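"""Gait events: kinematic event detection, two-rater freeze-annotation
merging with agreement metrics, event-selection rules and behavioural
statistics.

Freezing of gait is annotated (here: generated) as intervals of absent or
markedly reduced forward foot progression.  Two raters' annotations are
merged by interval union when they overlap within a tolerance
(default 2 s, correction = include); non-matching annotations are
surfaced as disputed.  Agreement is summarised by positive/negative
agreement and the prevalence index on a sampled timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import EventTable, Kinematics


# ---------------------------------------------------------------- detection


@dataclass
class ProtocolGeometry:
    """Corridor geometry for kinematic event definitions."""

    door_x_m: float            # door plane along the corridor axis
    square_half_width_m: float = 1.0
    square_x_m: tuple = (0.0, float("nan"))  # positions of the two squares


def detect_gait_events(kin: Kinematics, geometry: ProtocolGeometry,
                       v_stop: float = 0.1, min_stop_s: float = 2.0,
                       omega_turn_deg_s: float = 30.0) -> EventTable:
    """Detect stops, starts, turns and doorway passages from kinematics.

    * stop: velocity below ``v_stop`` for at least ``min_stop_s``;
    * start: velocity rising above ``v_stop`` after a stop;
    * turn: yaw angular speed above ``omega_turn_deg_s`` while inside a
      turning square;
    * doorway: the position trace crosses the door plane.
    """
    fs = kin.fs_hz
    v = kin.series["body_velocity"][0]
    rows = []

    walking = v > 0.3
    v_walk = float(np.median(v[walking])) if walking.any() else 1.0
    v_half = max(v_stop, 0.5 * v_walk)

    def _refine_down(idx: int) -> float:
        # walk back from the below-threshold episode start to the
        # half-cruise-speed crossing (the midpoint of the braking ramp)
        j = idx
        while j > 0 and v[j] < v_half:
            j -= 1
        return j / fs

    def _refine_up(idx: int) -> float:
        j = idx
        while j < len(v) - 1 and v[j] < v_half:
            j += 1
        return j / fs

    below = v < v_stop
    edges = np.diff(below.astype(int))
    starts_idx = list(np.flatnonzero(edges == 1) + 1)
    if below[0]:
        starts_idx = [0] + starts_idx
    for s in starts_idx:
        e = s
        while e < len(below) and below[e]:
            e += 1
        if (e - s) / fs >= min_stop_s:
            onset = _refine_down(s) if s > 0 else 0.0
            rows.append(dict(onset=onset, duration=e / fs - onset, trial_type="stop",
                             trigger="none", source="kinematics"))
            if e < len(below):
                rows.append(dict(onset=_refine_up(e), duration=0.0, trial_type="start",
                                 trigger="none", source="kinematics"))

    pos = kin.series["body_position"]
    have_position = np.isfinite(pos[0]).all()
    x = pos[0] if have_position else None

    # turns: yaw angular speed (integrated head angular acceleration,
    # detrended against integration drift) above threshold inside a square
    angacc = kin.series["head_angular_acceleration"][0]  # rad/s^2
    omega = np.degrees(np.cumsum(angacc) / fs)
    omega = omega - _boxcar(omega, int(fs * 10.0) | 1)
    omega = np.abs(_boxcar(omega, int(fs * 0.3) | 1))
    turning = omega > omega_turn_deg_s
    if have_position and np.isfinite(geometry.square_x_m).all():
        in_square = np.zeros_like(turning)
        for sx in geometry.square_x_m:
            in_square |= np.abs(x - sx) < geometry.square_half_width_m
        turning &= in_square
    e2 = np.diff(turning.astype(int))
    t_starts = list(np.flatnonzero(e2 == 1) + 1)
    if turning[0]:
        t_starts = [0] + t_starts
    low = 5.0
    for s in t_starts:
        e = s
        while e < len(turning) and turning[e]:
            e += 1
        if (e - s) / fs >= 0.5:
            j = s
            while j > 0 and omega[j] > low:
                j -= 1  # refine onset back to where rotation began
            rows.append(dict(onset=j / fs, duration=(e - j) / fs,
                             trial_type="turn_left", trigger="none",
                             source="kinematics"))

    if have_position:
        crossing = np.flatnonzero(np.diff(np.sign(x - geometry.door_x_m)) != 0)
        last = -np.inf
        for c in crossing:
            t = c / fs
            if t - last > 3.0:  # debounce repeated sign flips at the plane
                rows.append(dict(onset=t, duration=0.0, trial_type="doorway",
                                 trigger="none", source="kinematics"))
                last = t
    else:
        import warnings

        warnings.warn("no position data; doorway events skipped")
    return EventTable(pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                                  "trigger", "source"]))


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    w = np.ones(n) / n
    return np.convolve(np.pad(x, (n // 2, n // 2), mode="edge"), w, mode="valid")[: len(x)]


# ---------------------------------------------------------------- merging


def merge_annotations(a: EventTable, b: EventTable, tolerance_s: float = 2.0,
                      correction: str = "include") -> tuple[EventTable, EventTable]:
    """Merge two raters' freeze annotations.

    Events whose intervals lie within ``tolerance_s`` of each other are
    combined; with ``correction="include"`` the consensus interval is the
    union.  Events with no counterpart within tolerance are returned as
    disputed (to be resolved by discussion).  Symmetric in its arguments.
    """
    if correction != "include":
        raise ValueError("only correction='include' is implemented")
    fa = a.of_type("freeze").df.copy()
    fb = b.of_type("freeze").df.copy()
    fa["rater_idx"], fb["rater_idx"] = 0, 1
    allv = pd.concat([fa, fb]).sort_values("onset").reset_index(drop=True)
    consensus_rows, disputed_rows = [], []
    cluster: list = []

    def close(ev1, ev2) -> bool:
        gap = max(ev1.onset, ev2.onset) - min(ev1.onset + ev1.duration,
                                              ev2.onset + ev2.duration)
        return gap <= tolerance_s

    def flush(cl):
        raters = {r.rater_idx for r in cl}
        onset = min(r.onset for r in cl)
        end = max(r.onset + r.duration for r in cl)
        trigger = cl[0].trigger
        if len(raters) == 2:
            consensus_rows.append(dict(onset=onset, duration=end - onset,
                                       trial_type="freeze", trigger=trigger,
                                       source="consensus"))
        else:
            for r in cl:
                disputed_rows.append(dict(onset=r.onset, duration=r.duration,
                                          trial_type="freeze", trigger=r.trigger,
                                          source=r.source))

    for ev in allv.itertuples():
        if cluster and any(close(ev, c) for c in cluster):
            cluster.append(ev)
        else:
            if cluster:
                flush(cluster)
            cluster = [ev]
    if cluster:
        flush(cluster)
    cols = ["onset", "duration", "trial_type", "trigger", "source"]
    return (EventTable(pd.DataFrame(consensus_rows, columns=cols)),
            EventTable(pd.DataFrame(disputed_rows, columns=cols)))


# ---------------------------------------------------------------- agreement


@dataclass
class AgreementSummary:
    positive_agreement: float
    negative_agreement: float
    prevalence_index: float
    n_samples: int
    sample_rate_hz: float
    counts: dict = field(default_factory=dict)
    note: str = ""


def _sampled_mask(table: EventTable, times: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for _, ev in table.of_type("freeze").df.iterrows():
        mask |= (times >= ev.onset) & (times < ev.onset + ev.duration)
    return mask


def agreement_metrics(a: EventTable, b: EventTable, total_duration_s: float,
                      sample_rate_hz: float = 1.0) -> AgreementSummary:
    """Positive/negative agreement and prevalence index on a sampled
    timeline.

    With per-sample counts n11 (both raters mark freezing), n10, n01 and
    n00: positive = 2 n11 / (2 n11 + n10 + n01), negative =
    2 n00 / (2 n00 + n10 + n01), prevalence index = (n11 - n00) / N.
    """
    n = int(round(total_duration_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    ma, mb = _sampled_mask(a, times), _sampled_mask(b, times)
    n11 = int(np.sum(ma & mb))
    n10 = int(np.sum(ma & ~mb))
    n01 = int(np.sum(~ma & mb))
    n00 = int(np.sum(~ma & ~mb))
    note = ""
    den_p = 2 * n11 + n10 + n01
    den_n = 2 * n00 + n10 + n01
    if den_p == 0:
        pos, note = float("nan"), "no freezing marked by either rater"
    else:
        pos = 2 * n11 / den_p
    neg = 2 * n00 / den_n if den_n else float("nan")
    return AgreementSummary(pos, neg, (n11 - n00) / n, n, sample_rate_hz,
                            counts=dict(n11=n11, n10=n10, n01=n01, n00=n00), note=note)


# ---------------------------------------------------------------- selection


def label_freeze_triggers(freezes: EventTable, detected: EventTable,
                          proximity_s: float = 5.0,
                          stop_positions: EventTable | None = None) -> EventTable:
    """Attribute each freeze to the trigger of the nearest detected gait
    event within ``proximity_s``, else "walking"; freezes just before a
    detected stop are labelled "destination"."""
    ttype_to_trigger = {"turn_left": "turn", "turn_right": "turn",
                        "doorway": "doorway", "start": "start", "stop": "destination"}
    det = detected.df
    out = freezes.df.copy()
    for i, ev in out.iterrows():
        best, best_d = "walking", proximity_s
        for _, d in det.iterrows():
            trig = ttype_to_trigger.get(d.trial_type)
            if trig is None:
                continue
            dist = abs(d.onset - ev.onset)
            if trig == "destination":
                dist = d.onset - ev.onset  # only freezes *approaching* the stop
                if dist < 0:
                    continue
            if dist <= best_d:
                best, best_d = trig, dist
        out.loc[i, "trigger"] = best
    return EventTable(out, validate=False)


def select_events(consensus_freezes: EventTable, detected_events: EventTable,
                  refractory_s: float = 10.0, clearance_s: float = 10.0) -> EventTable:
    """Apply the event-selection rules and pool into an analysis table.

    A freeze is retained only when no earlier freeze ends within
    ``refractory_s`` before its onset; a successful (non-freeze) gait
    event is retained only when no freeze intersects
    ``[onset - clearance_s, onset + clearance_s]``.  Idempotent.
    """
    frz = consensus_freezes.of_type("freeze").df.sort_values("onset")
    kept_frz = []
    last_end = -np.inf
    for _, ev in frz.iterrows():
        if ev.onset - last_end > refractory_s:
            kept_frz.append(ev)
        last_end = max(last_end, ev.onset + ev.duration)
    kept_rows = list(kept_frz)
    for _, ev in detected_events.df.iterrows():
        if ev.trial_type in ("freeze", "stand"):
            continue
        clear = True
        for _, f in frz.iterrows():
            if f.onset < ev.onset + clearance_s and f.onset + f.duration > ev.onset - clearance_s:
                clear = False
                break
        if clear:
            kept_rows.append(ev)
    cols = ["onset", "duration", "trial_type", "trigger", "source"]
    out = pd.DataFrame(kept_rows, columns=cols) if kept_rows else pd.DataFrame(columns=cols)
    return EventTable(out, validate=False)


def percent_time_frozen(consensus: EventTable, task_duration_s: float,
                        trigger: str | None = None) -> float:
    """Union length of (optionally trigger-filtered) freeze intervals as a
    percentage of the task duration."""
    df = consensus.of_type("freeze").df
    if trigger is not None:
        df = df[df["trigger"] == trigger]
    if len(df) == 0:
        return 0.0
    iv = sorted((r.onset, r.onset + r.duration) for r in df.itertuples())
    total = 0.0
    cur_s, cur_e = iv[0]
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return 100.0 * total / task_duration_s


# ---------------------------------------------------------------- behaviour


@dataclass
class BehaviourWindows:
    """Window definitions (s relative to event onset) for speed summaries."""

    stop: tuple = (-3.0, 0.0)      # deceleration over the last 3 s before stopping
    turn: tuple = (-2.0, 0.0)      # deceleration over the 2 s before the turn
    doorway: tuple = (-2.0, 0.0)
    start: tuple = (0.0, 3.0)      # acceleration over the first 3 s after starting


def event_window_stats(kin: Kinematics, events: EventTable,
                       windows: BehaviourWindows | None = None) -> pd.DataFrame:
    """Mean speed and mean acceleration in the stated window around each
    stop/turn/doorway/start event."""
    windows = windows or BehaviourWindows()
    fs = kin.fs_hz
    v = kin.series["body_velocity"][0]
    wmap = {"stop": windows.stop, "turn_left": windows.turn, "turn_right": windows.turn,
            "doorway": windows.doorway, "start": windows.start}
    rows = []
    for _, ev in events.df.iterrows():
        w = wmap.get(ev.trial_type)
        if w is None:
            continue
        i0 = int((ev.onset + w[0]) * fs)
        i1 = int((ev.onset + w[1]) * fs)
        if i0 < 0 or i1 > len(v) or i1 <= i0 + 1:
            continue
        seg = v[i0:i1]
        accel = (seg[-1] - seg[0]) / (w[1] - w[0])
        rows.append(dict(trial_type=ev.trial_type, onset=ev.onset,
                         mean_speed=float(seg.mean()), accel=float(accel)))
    return pd.DataFrame(rows, columns=["trial_type", "onset", "mean_speed", "accel"])


def behaviour_stats(per_participant: pd.DataFrame, value: str = "accel",
                    group_col: str = "group") -> pd.DataFrame:
    """Welch two-sample (PD vs HC) and per-group one-sample t statistics on
    participant-level window summaries.

    ``per_participant`` must have one row per participant with columns
    ``group`` and the value column (already averaged within participant).
    """
    out = []
    groups = per_participant.groupby(group_col)[value]
    vals = {g: v.to_numpy() for g, v in groups}
    for g, v in vals.items():
        if len(v) >= 2:
            t, p = stats.ttest_1samp(v, 0.0)
        else:
            t, p = np.nan, np.nan
        out.append(dict(test=f"one_sample_{g}", mean=float(np.mean(v)),
                        t=float(t), p=float(p), n=len(v)))
    if len(vals) == 2:
        (g1, v1), (g2, v2) = sorted(vals.items())
        if len(v1) >= 2 and len(v2) >= 2:
            t, p = stats.ttest_ind(v1, v2, equal_var=False)
            out.append(dict(test=f"two_sample_{g1}_vs_{g2}",
                            mean=float(np.mean(v1) - np.mean(v2)),
                            t=float(t), p=float(p), n=len(v1) + len(v2)))
    return pd.DataFrame(out)
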