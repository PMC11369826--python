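"""Event-locked epoching, baseline correction and ROI averaging.

The outcome variable downstream is the mean ΔHbO in a window after event
onset (early 0-3 s; additionally late 7-10 s for stops and starts),
baseline-corrected by the mean over -10 to -5 s before onset (a stable
walking/standing reference recorded before the instruction was given).
Windows are closed-open ``[a, b)`` in seconds from onset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import EventTable, Montage, Recording

log = logging.getLogger(__name__)

EARLY_WINDOW = (0.0, 3.0)
LATE_WINDOW = (7.0, 10.0)
BASELINE = (-10.0, -5.0)

_TYPE_TO_CONDITION = {
    "turn_left": "turn", "turn_right": "turn", "doorway": "doorway",
    "stop": "stop", "start": "start", "freeze": "freeze",
}

EPOCH_COLUMNS = ["participant", "group", "subgroup", "run", "event_id", "condition",
                 "direction", "roi_or_channel", "window", "value",
                 "pct_time_frozen", "updrs"]


def epoch_events(z: Recording, events: EventTable, montage: Montage,
                 window: tuple[float, float] = EARLY_WINDOW,
                 baseline: tuple[float, float] = BASELINE,
                 window_name: str = "early", chromophore: str = "HbO",
                 participant: str = "sub-01", group: str = "PD",
                 meta: dict | None = None) -> pd.DataFrame:
    """Channel-level epoch table: value = mean(window) - mean(baseline).

    Events whose window or baseline falls outside the recording are
    dropped (count logged).  Rows from pruned channels are excluded.
    """
    meta = meta or {}
    fs = z.fs_hz
    n = z.n_samples
    keep = z.unmasked_row_indices()
    rows_meta = z.rows.iloc[keep]
    chromo_sel = rows_meta["chromophore"] == chromophore
    keep = keep[chromo_sel.to_numpy()]
    rows_meta = z.rows.iloc[keep]

    out = []
    dropped = 0
    for ei, ev in events.df.iterrows():
        cond = _TYPE_TO_CONDITION.get(ev.trial_type)
        if cond is None:
            continue
        t0 = ev.onset - z.time0_s
        i0, i1 = int(round((t0 + window[0]) * fs)), int(round((t0 + window[1]) * fs))
        b0, b1 = int(round((t0 + baseline[0]) * fs)), int(round((t0 + baseline[1]) * fs))
        if b0 < 0 or i1 > n or i1 <= i0 or b1 <= b0:
            dropped += 1
            continue
        vals = z.data[keep, i0:i1].mean(axis=1) - z.data[keep, b0:b1].mean(axis=1)
        direction = {"turn_left": "left", "turn_right": "right"}.get(ev.trial_type, "none")
        for ch, val in zip(rows_meta["channel"], vals):
            out.append(dict(
                participant=participant, group=group,
                subgroup=meta.get("subgroup", "none"), run=z.run_id,
                event_id=f"{z.run_id}:{ei}", condition=cond, direction=direction,
                roi_or_channel=ch, window=window_name, value=float(val),
                pct_time_frozen=meta.get("pct_time_frozen", np.nan),
                updrs=meta.get("updrs", np.nan)))
    if dropped:
        log.info("epoch_events: dropped %d events lacking window/baseline margin", dropped)
    return pd.DataFrame(out, columns=EPOCH_COLUMNS)


def roi_average(table: pd.DataFrame, montage: Montage) -> pd.DataFrame:
    """Average channel-level rows into ROI-level rows (unweighted mean over
    the channels mapped to each ROI; ROIs left without channels are absent)."""
    if len(table) == 0:
        return table.copy()
    roi_map = {c.id: c.roi for c in montage.channels if c.kind == "long"}
    t = table.copy()
    t["roi"] = t["roi_or_channel"].map(roi_map)
    t = t[t["roi"].notna() & (t["roi"] != "none")]
    keys = [c for c in EPOCH_COLUMNS if c not in ("roi_or_channel", "value")]
    out = (t.groupby(keys + ["roi"], dropna=False, sort=False)["value"]
           .mean().reset_index())
    out = out.rename(columns={"roi": "roi_or_channel"})
    return out[EPOCH_COLUMNS]


def pool_turns(table: pd.DataFrame) -> pd.DataFrame:
    """Left and right turns are pooled into one "turn" condition; the
    direction column is retained for audit.  Idempotent."""
    t = table.copy()
    sel = t["condition"].isin(["turn_left", "turn_right"])
    if sel.any():
        t.loc[sel & (t["direction"] == "none"), "direction"] = (
            t.loc[sel, "condition"].str.replace("turn_", "", regex=False))
        t.loc[sel, "condition"] = "turn"
    return t
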