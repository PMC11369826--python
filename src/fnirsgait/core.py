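"""Core data model: montages, recordings, kinematics and event tables.

The in-memory containers used throughout the pipeline.  Conventions:

* time is in seconds, 0-based from run start; events are half-open
  intervals ``[onset, onset + duration)``;
* channel identity is a ``"S#-D#"`` string; a measurement row is a
  channel at a wavelength (``"S1-D1@760"``) before conversion to
  haemoglobin, or a channel/chromophore pair (``"S1-D1:HbO"``) after;
* a :class:`Recording` holds one run of uniformly sampled data as a
  ``rows x samples`` matrix plus a row-metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROIS = ("M1", "PMC", "SMA", "PFC", "PPC")
EVENT_TYPES = ("turn_left", "turn_right", "doorway", "stop", "start", "freeze", "stand")
TRIGGERS = ("turn", "doorway", "start", "destination", "walking", "none")
EVENT_COLUMNS = ["onset", "duration", "trial_type", "trigger", "source"]


class FormatError(ValueError):
    """Raised when an on-disk container violates the I/O contract."""


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    id: str
    source_id: int
    detector_id: int
    interoptode_distance_mm: float
    kind: str  # "long" | "short"
    roi: str   # one of ROIS or "none"
    hemisphere: str  # "L" | "R" | "mid"


@dataclass(frozen=True)
class Montage:
    """Channel geometry and semantics for one cap layout."""

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.wavelengths_nm) != 2:
            raise FormatError("montage must declare exactly two wavelengths")
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate channel ids in montage")
        for c in self.channels:
            if c.kind == "short":
                if c.interoptode_distance_mm != 10:
                    raise FormatError(f"short channel {c.id} must have 10 mm distance")
            elif c.kind == "long":
                if c.interoptode_distance_mm != 30:
                    raise FormatError(f"long channel {c.id} must have 30 mm distance")
                if c.roi not in ROIS + ("none",):
                    raise FormatError(f"long channel {c.id} has unknown ROI {c.roi!r}")
            else:
                raise FormatError(f"channel {c.id} has unknown kind {c.kind!r}")

    @property
    def long_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "long")

    @property
    def short_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "short")

    def channel(self, cid: str) -> Channel:
        for c in self.channels:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def roi_of(self, cid: str) -> str:
        return self.channel(cid).roi


def default_montage() -> Montage:
    """The default cap layout: 32 long (30 mm) + 16 short (10 mm) channels.

    Long channels cover the five motor-related ROIs bilaterally (SMA has a
    midline pair); every second source additionally carries a short channel.
    """
    plan = [
        # (roi, n_per_hemisphere)
        ("PFC", 4), ("PMC", 3), ("SMA", 3), ("M1", 3), ("PPC", 3),
    ]
    channels: list[Channel] = []
    src = 1
    det = 1
    for roi, n in plan:
        for hemi in ("L", "R"):
            for _ in range(n):
                cid = f"S{src}-D{det}"
                channels.append(Channel(cid, src, det, 30.0, "long", roi, hemi))
                src += 1
                det += 1
    # 32 long channels total (4+3+3+3+3)*2 = 32
    assert len(channels) == 32
    for i in range(16):
        base = channels[2 * i]  # every second long channel's source gets a short pair
        cid = f"S{base.source_id}-D{100 + i}"
        channels.append(
            Channel(cid, base.source_id, 100 + i, 10.0, "short", "none", base.hemisphere)
        )
    return Montage(tuple(channels))


@dataclass
class Recording:
    """One run of uniformly sampled multi-channel data.

    ``data`` is ``rows x samples``; ``rows`` is a DataFrame with columns
    ``channel`` (str), ``wavelength_nm`` (float, NaN after conversion to
    haemoglobin) and ``chromophore`` ("HbO"/"HbR"/"n/a").
    """

    data: np.ndarray
    fs_hz: float
    unit: str  # raw_intensity | optical_density | micromolar | zscore
    rows: pd.DataFrame
    run_id: str = "run-01"
    time0_s: float = 0.0
    pruned: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be rows x samples")
        if len(self.rows) != self.data.shape[0]:
            raise ValueError("row metadata does not match data")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.rows = self.rows.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return self.time0_s + np.arange(self.n_samples) / self.fs_hz

    def copy(self, **changes) -> "Recording":
        base = dict(
            data=self.data.copy(),
            fs_hz=self.fs_hz,
            unit=self.unit,
            rows=self.rows.copy(),
            run_id=self.run_id,
            time0_s=self.time0_s,
            pruned=self.pruned,
        )
        base.update(changes)
        return Recording(**base)

    def row_labels(self) -> list[str]:
        labels = []
        for _, r in self.rows.iterrows():
            if isinstance(r["chromophore"], str) and r["chromophore"] in ("HbO", "HbR"):
                labels.append(f"{r['channel']}:{r['chromophore']}")
            else:
                labels.append(f"{r['channel']}@{int(r['wavelength_nm'])}")
        return labels

    def select(self, mask: np.ndarray) -> "Recording":
        """Sub-recording with the given boolean/index row selection."""
        mask = np.asarray(mask)
        return self.copy(data=self.data[mask], rows=self.rows.iloc[mask].reset_index(drop=True))

    def unmasked_row_indices(self) -> np.ndarray:
        keep = ~self.rows["channel"].isin(self.pruned)
        return np.flatnonzero(keep.to_numpy())


KINEMATIC_SERIES = {
    "head_acceleration": 3,        # m/s^2
    "head_angular_acceleration": 3,  # rad/s^2
    "head_neck_orientation": 3,    # deg: yaw, pitch, roll
    "body_velocity": 1,            # m/s
    "body_position": 2,            # m
}


@dataclass
class Kinematics:
    """Head/body movement time series on a uniform clock (default 60 Hz)."""

    fs_hz: float
    series: dict
    run_id: str = "run-01"
    time0_s: float = 0.0

    def __post_init__(self) -> None:
        n = None
        for name, width in KINEMATIC_SERIES.items():
            if name not in self.series:
                raise ValueError(f"missing kinematic series {name!r}")
            arr = np.atleast_2d(np.asarray(self.series[name], dtype=float))
            if arr.shape[0] != width:
                arr = arr.reshape(width, -1)
            self.series[name] = arr
            if n is None:
                n = arr.shape[1]
            elif arr.shape[1] != n:
                raise ValueError("kinematic series have unequal lengths")
        self._n = n

    @property
    def n_samples(self) -> int:
        return self._n

    @property
    def duration_s(self) -> float:
        return self._n / self.fs_hz

    def times(self) -> np.ndarray:
        return self.time0_s + np.arange(self._n) / self.fs_hz

    def copy(self, **changes) -> "Kinematics":
        base = dict(
            fs_hz=self.fs_hz,
            series={k: v.copy() for k, v in self.series.items()},
            run_id=self.run_id,
            time0_s=self.time0_s,
        )
        base.update(changes)
        return Kinematics(**base)


class EventTable:
    """Typed event intervals for one run, sorted by onset.

    Wraps a DataFrame with columns ``onset, duration, trial_type,
    trigger, source``.  Intervals are half-open ``[onset, onset+duration)``.
    """

    def __init__(self, df: pd.DataFrame | None = None, validate: bool = True):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        df = df.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                if col == "trigger":
                    df[col] = "none"
                elif col == "source":
                    df[col] = "protocol"
                else:
                    raise FormatError(f"event table missing column {col!r}")
        df = df[EVENT_COLUMNS]
        df["onset"] = df["onset"].astype(float)
        df["duration"] = df["duration"].astype(float)
        df = df.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
        self.df = df
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if (df["onset"] < 0).any():
            raise FormatError("event onsets must be >= 0")
        if (df["duration"] < 0).any():
            raise FormatError("event durations must be >= 0")
        bad = ~df["trial_type"].isin(EVENT_TYPES)
        if bad.any():
            raise FormatError(f"unknown trial_type values: {sorted(df.loc[bad, 'trial_type'].unique())}")
        frz = df[df["trial_type"] == "freeze"]
        if (frz["trigger"] == "none").any():
            raise FormatError("freeze events must carry a trigger")
        # duplicate consensus freezes that overlap are a validation error
        cons = frz[frz["source"] == "consensus"]
        if len(cons) > 1:
            onsets = cons["onset"].to_numpy()
            ends = onsets + cons["duration"].to_numpy()
            if np.any(onsets[1:] < ends[:-1]):
                raise FormatError("overlapping duplicate consensus freeze rows")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        return bool(
            np.allclose(self.df[["onset", "duration"]], other.df[["onset", "duration"]])
            and (self.df[["trial_type", "trigger", "source"]].to_numpy()
                 == other.df[["trial_type", "trigger", "source"]].to_numpy()).all()
        )

    def of_type(self, *types: str) -> "EventTable":
        return EventTable(self.df[self.df["trial_type"].isin(types)], validate=False)

    def from_source(self, *sources: str) -> "EventTable":
        return EventTable(self.df[self.df["source"].isin(sources)], validate=False)

    @staticmethod
    def from_rows(rows: list[dict]) -> "EventTable":
        return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))

    def shift(self, dt: float) -> "EventTable":
        df = self.df.copy()
        df["onset"] = df["onset"] + dt
        return EventTable(df, validate=False)


def align_streams(
    recording: Recording,
    kinematics: Kinematics,
    sync_offsets_s: tuple[float, float] = (0.0, 0.0),
) -> tuple[Recording, Kinematics]:
    """Put an fNIRS recording and a kinematics stream on a common clock.

    ``sync_offsets_s = (rec_offset, kin_offset)`` are the known start times
    of each stream on the shared lab clock (sync offsets are measured by the
    acquisition setup and are an *input* here).  Both streams are cropped to
    their temporal overlap and re-referenced so that time 0 is the overlap
    start.
    """
    r_off, k_off = sync_offsets_s
    if not (np.isfinite(r_off) and np.isfinite(k_off)):
        raise ValueError("sync offsets must be finite")
    r0, r1 = r_off + recording.time0_s, r_off + recording.time0_s + recording.duration_s
    k0, k1 = k_off + kinematics.time0_s, k_off + kinematics.time0_s + kinematics.duration_s
    t0, t1 = max(r0, k0), min(r1, k1)
    if t1 <= t0:
        raise ValueError("streams have no temporal overlap")

    ri0 = int(round((t0 - r0) * recording.fs_hz))
    ri1 = int(round((t1 - r0) * recording.fs_hz))
    ki0 = int(round((t0 - k0) * kinematics.fs_hz))
    ki1 = int(round((t1 - k0) * kinematics.fs_hz))
    rec = recording.copy(data=recording.data[:, ri0:ri1], time0_s=0.0)
    kin = kinematics.copy(
        series={k: v[:, ki0:ki1] for k, v in kinematics.series.items()}, time0_s=0.0
    )
    return rec, kin
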