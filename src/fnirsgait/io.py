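"""Readers and writers: SNIRF-style HDF5, tabular TSV fallback, BIDS-style
events tables, kinematics TSV and montage JSON.

The HDF5 layout follows the SNIRF convention (``/nirs/data1/dataTimeSeries``
with a measurement list, ``/nirs/probe/wavelengths``) restricted to the
fields this pipeline needs; the TSV dialect stores the same content as a
wide table plus a JSON sidecar so fixtures stay human-readable.  Round
trips preserve every numeric field at full float64 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    Channel,
    EventTable,
    FormatError,
    Kinematics,
    KINEMATIC_SERIES,
    Montage,
    Recording,
)

# ---------------------------------------------------------------- montage


def montage_to_dict(montage: Montage) -> dict:
    return {
        "wavelengths_nm": list(montage.wavelengths_nm),
        "channels": [
            {
                "id": c.id,
                "source_id": c.source_id,
                "detector_id": c.detector_id,
                "interoptode_distance_mm": c.interoptode_distance_mm,
                "kind": c.kind,
                "roi": c.roi,
                "hemisphere": c.hemisphere,
            }
            for c in montage.channels
        ],
    }


def montage_from_dict(d: dict) -> Montage:
    if "wavelengths_nm" not in d or "channels" not in d:
        raise FormatError("montage dict missing wavelengths_nm/channels")
    chans = tuple(
        Channel(
            id=c["id"],
            source_id=int(c["source_id"]),
            detector_id=int(c["detector_id"]),
            interoptode_distance_mm=float(c["interoptode_distance_mm"]),
            kind=c["kind"],
            roi=c["roi"],
            hemisphere=c["hemisphere"],
        )
        for c in d["channels"]
    )
    return Montage(chans, tuple(float(w) for w in d["wavelengths_nm"]))


def write_montage(path, montage: Montage) -> None:
    Path(path).write_text(json.dumps(montage_to_dict(montage), indent=1))


def load_montage(path) -> Montage:
    return montage_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------- recordings


def write_recording(path, recording: Recording, montage: Montage) -> None:
    """Write a recording; dialect chosen by extension (.h5/.snirf vs .tsv)."""
    path = Path(path)
    if path.suffix in (".h5", ".snirf", ".hdf5"):
        _write_snirf_like(path, recording, montage)
    elif path.suffix == ".tsv":
        _write_tsv(path, recording, montage)
    else:
        raise FormatError(f"unknown recording extension {path.suffix!r}")


def load_recording(path, fmt: str | None = None) -> tuple[Recording, Montage]:
    """Load a recording and its montage.

    ``fmt`` may be ``"snirf_like"`` or ``"tsv"``; by default it is inferred
    from the extension.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix == ".tsv" else "snirf_like"
    if fmt == "snirf_like":
        return _load_snirf_like(path)
    if fmt == "tsv":
        return _load_tsv(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def _row_metadata_arrays(recording: Recording):
    chan = recording.rows["channel"].to_numpy(dtype=object)
    wl = recording.rows["wavelength_nm"].to_numpy(dtype=float)
    chromo = recording.rows["chromophore"].to_numpy(dtype=object)
    return chan, wl, chromo


def _write_snirf_like(path: Path, recording: Recording, montage: Montage) -> None:
    chan, wl, chromo = _row_metadata_arrays(recording)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0-like")
        nirs = f.create_group("nirs")
        nirs.attrs["run_id"] = recording.run_id
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=recording.data.T)  # time x rows
        data1.create_dataset(
            "time", data=recording.time0_s + np.arange(recording.n_samples) / recording.fs_hz
        )
        data1.attrs["unit"] = recording.unit
        ml = data1.create_group("measurementList")
        str_dt = h5py.string_dtype()
        ml.create_dataset("channel", data=[str(x) for x in chan], dtype=str_dt)
        ml.create_dataset("wavelength_nm", data=wl)
        ml.create_dataset("chromophore", data=[str(x) for x in chromo], dtype=str_dt)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(montage.wavelengths_nm))
        probe.create_dataset("montage_json", data=json.dumps(montage_to_dict(montage)), dtype=str_dt)
        if recording.pruned:
            nirs.create_dataset(
                "pruned", data=[str(x) for x in sorted(recording.pruned)], dtype=str_dt
            )


def _check_uniform(time: np.ndarray) -> float:
    if len(time) < 2:
        raise FormatError("recording has fewer than two samples")
    dt = np.diff(time)
    if np.ptp(dt) > 1e-6 * np.median(dt):
        raise FormatError("non-uniform sampling rejected")
    return 1.0 / float(np.median(dt))


def _load_snirf_like(path: Path) -> tuple[Recording, Montage]:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        try:
            data1 = f["nirs/data1"]
            probe = f["nirs/probe"]
            wavelengths = np.asarray(probe["wavelengths"])
        except KeyError as e:
            raise FormatError(f"missing group in container: {e}") from e
        if wavelengths.size != 2:
            raise FormatError("container must declare exactly two wavelengths")
        if "montage_json" not in probe:
            raise FormatError("missing channel metadata (montage)")
        montage = montage_from_dict(json.loads(probe["montage_json"][()].decode()))
        time = np.asarray(data1["time"])
        fs = _check_uniform(time)
        ml = data1["measurementList"]
        rows = pd.DataFrame(
            {
                "channel": [s.decode() for s in ml["channel"][()]],
                "wavelength_nm": np.asarray(ml["wavelength_nm"]),
                "chromophore": [s.decode() for s in ml["chromophore"][()]],
            }
        )
        pruned = frozenset(
            s.decode() for s in f["nirs/pruned"][()]
        ) if "nirs/pruned" in f else frozenset()
        rec = Recording(
            data=np.asarray(data1["dataTimeSeries"]).T,
            fs_hz=fs,
            unit=data1.attrs["unit"],
            rows=rows,
            run_id=f["nirs"].attrs.get("run_id", "run-01"),
            time0_s=float(time[0]),
            pruned=pruned,
        )
    return rec, montage


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_tsv(path: Path, recording: Recording, montage: Montage) -> None:
    labels = recording.row_labels()
    df = pd.DataFrame(recording.data.T, columns=labels)
    df.insert(0, "time", recording.times())
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    chan, wl, chromo = _row_metadata_arrays(recording)
    meta = {
        "unit": recording.unit,
        "fs_hz": recording.fs_hz,
        "run_id": recording.run_id,
        "time0_s": recording.time0_s,
        "pruned": sorted(recording.pruned),
        "rows": [
            {"channel": c, "wavelength_nm": None if np.isnan(w) else w, "chromophore": ch}
            for c, w, ch in zip(chan, wl, chromo)
        ],
        "montage": montage_to_dict(montage),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _load_tsv(path: Path) -> tuple[Recording, Montage]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side.name} with channel/wavelength metadata")
    meta = json.loads(side.read_text())
    if "montage" not in meta or "rows" not in meta:
        raise FormatError("sidecar missing montage/row metadata")
    montage = montage_from_dict(meta["montage"])
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    fs = _check_uniform(df["time"].to_numpy())
    rows = pd.DataFrame(
        {
            "channel": [r["channel"] for r in meta["rows"]],
            "wavelength_nm": [
                np.nan if r["wavelength_nm"] is None else float(r["wavelength_nm"])
                for r in meta["rows"]
            ],
            "chromophore": [r["chromophore"] for r in meta["rows"]],
        }
    )
    data = df.drop(columns="time").to_numpy().T
    rec = Recording(
        data=data,
        fs_hz=fs,
        unit=meta["unit"],
        rows=rows,
        run_id=meta.get("run_id", "run-01"),
        time0_s=float(df["time"].iloc[0]),
        pruned=frozenset(meta.get("pruned", [])),
    )
    return rec, montage


# ---------------------------------------------------------------- events


def write_events(path, table: EventTable) -> None:
    """BIDS-style events TSV: onset, duration, trial_type, trigger, source."""
    table.validate()
    df = table.df.rename(columns={})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_events(path) -> EventTable:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise FormatError(f"events table missing columns {missing}")
    if len(df) == 0:
        return EventTable()
    return EventTable(df)


# ---------------------------------------------------------------- kinematics

_KIN_COLUMNS = {
    "head_acceleration": ["head_accel_x", "head_accel_y", "head_accel_z"],
    "head_angular_acceleration": ["head_angaccel_x", "head_angaccel_y", "head_angaccel_z"],
    "head_neck_orientation": ["head_neck_yaw", "head_neck_pitch", "head_neck_roll"],
    "body_velocity": ["body_velocity"],
    "body_position": ["body_pos_x", "body_pos_y"],
}


def write_kinematics(path, kin: Kinematics) -> None:
    cols = {"time": kin.times()}
    for name, labels in _KIN_COLUMNS.items():
        arr = kin.series[name]
        for i, lab in enumerate(labels):
            cols[lab] = arr[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_kinematics(path, run_id: str = "run-01") -> Kinematics:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    fs = _check_uniform(df["time"].to_numpy())
    series = {}
    for name, labels in _KIN_COLUMNS.items():
        missing = [c for c in labels if c not in df.columns]
        if missing:
            raise FormatError(f"kinematics table missing columns {missing}")
        series[name] = np.vstack([df[c].to_numpy() for c in labels])
    return Kinematics(fs_hz=fs, series=series, run_id=run_id, time0_s=float(df["time"].iloc[0]))
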