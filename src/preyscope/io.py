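"""File-format codecs: schedule/eye/event/ROI CSV dialects, trace stores.

All tables are plain CSV; trace matrices go to HDF5 (or NPZ, chosen by
file extension).  Every codec round-trips its numeric fields losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import SaccadeEvent
from .rois import ROIRecord
from .stimulus import StimulusEpoch
from .synthdata.eyes import EyeTrace


class ParseError(ValueError):
    pass


# --- schedule ---------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "epoch_index", "stimulus_id", "direction", "speed", "size", "polarity",
    "epoch_onset", "plane",
]


def write_schedule(schedule: Sequence[StimulusEpoch], path) -> None:
    rows = []
    for ep in schedule:
        code = ep.feature_code if ep.feature_code is not None else (-1, -1, -1, -1)
        rows.append([ep.epoch_index, ep.stimulus_id, *code, ep.epoch_onset, ep.plane])
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def read_schedule(path) -> list[StimulusEpoch]:
    df = _read_csv(path, SCHEDULE_COLUMNS[:2])
    return [
        StimulusEpoch(
            epoch_index=int(r.epoch_index),
            stimulus_id=int(r.stimulus_id),
            epoch_onset=float(r.epoch_onset),
            plane=int(getattr(r, "plane", 0)),
        )
        for r in df.itertuples()
    ]


# --- eye traces -------------------------------------------------------------

def write_eye_trace(trace: EyeTrace, path) -> None:
    pd.DataFrame(
        {"t": trace.t, "left_deg": trace.left, "right_deg": trace.right}
    ).to_csv(path, index=False)


def read_eye_trace(path) -> EyeTrace:
    df = _read_csv(path, ["t", "left_deg", "right_deg"])
    t = df["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 60.0
    return EyeTrace(
        left=df["left_deg"].to_numpy(),
        right=df["right_deg"].to_numpy(),
        fs=round(fs, 6),
        t0=float(t[0]) if len(t) else 0.0,
    )


# --- saccade events ---------------------------------------------------------

EVENT_COLUMNS = [
    "onset_time", "pre_left", "pre_right", "post_left", "post_right",
    "delta_left", "delta_right", "peak_velocity_left", "peak_velocity_right",
    "evoked", "epoch_index", "spot_azimuth_at_event",
]


def write_events(events: Sequence[SaccadeEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            [
                e.onset_time, e.pre_left, e.pre_right, e.post_left, e.post_right,
                e.delta_left, e.delta_right, e.peak_velocity_left,
                e.peak_velocity_right, int(e.evoked),
                -1 if e.epoch_index is None else e.epoch_index,
                np.nan if e.spot_azimuth_at_event is None else e.spot_azimuth_at_event,
            ]
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[SaccadeEvent]:
    df = _read_csv(path, ["onset_time", "evoked"])
    out = []
    for r in df.itertuples():
        az = getattr(r, "spot_azimuth_at_event", np.nan)
        out.append(
            SaccadeEvent(
                onset_time=float(r.onset_time),
                pre_left=float(r.pre_left),
                pre_right=float(r.pre_right),
                post_left=float(r.post_left),
                post_right=float(r.post_right),
                delta_left=float(r.delta_left),
                delta_right=float(r.delta_right),
                peak_velocity_left=float(r.peak_velocity_left),
                peak_velocity_right=float(r.peak_velocity_right),
                evoked=bool(r.evoked),
                epoch_index=None if int(r.epoch_index) < 0 else int(r.epoch_index),
                spot_azimuth_at_event=None if np.isnan(az) else float(az),
            )
        )
    return out


# --- ROI tables -------------------------------------------------------------

ROI_COLUMNS = ["roi_id", "fish_id", "plane_z", "x", "y", "hemisphere", "region"]


def write_rois(rois: Sequence[ROIRecord], path) -> None:
    pd.DataFrame(
        [
            [r.roi_id, r.fish_id, r.plane_z, r.x, r.y, r.hemisphere, r.region]
            for r in rois
        ],
        columns=ROI_COLUMNS,
    ).to_csv(path, index=False)


def read_rois(path) -> list[ROIRecord]:
    df = _read_csv(path, ["roi_id", "x", "y"])
    return [
        ROIRecord(
            roi_id=int(r.roi_id),
            fish_id=int(r.fish_id),
            plane_z=float(r.plane_z),
            x=float(r.x),
            y=float(r.y),
            hemisphere=str(r.hemisphere),
            region=str(r.region),
        )
        for r in df.itertuples()
    ]


# --- trace stores -----------------------------------------------------------

def write_trace_store(traces: np.ndarray, roi_ids: Sequence[int], path) -> None:
    """(n_frames, n_rois) ΔF/F matrix; HDF5 or NPZ by extension."""
    path = Path(path)
    traces = np.asarray(traces, dtype=float)
    ids = np.asarray(roi_ids, dtype=np.int64)
    if traces.ndim != 2 or traces.shape[1] != ids.size:
        raise ValueError("traces must be (n_frames, n_rois) matching roi_ids")
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=traces)
            f.create_dataset("roi_ids", data=ids)
    elif path.suffix == ".npz":
        np.savez(path, traces=traces, roi_ids=ids)
    else:
        raise ValueError(f"unsupported trace-store extension '{path.suffix}'")


def read_trace_store(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return f["traces"][()], f["roi_ids"][()]
    if path.suffix == ".npz":
        with np.load(path) as f:
            return f["traces"], f["roi_ids"]
    raise ValueError(f"unsupported trace-store extension '{path.suffix}'")


# --- ground truth -----------------------------------------------------------

def write_ground_truth_json(truth, events, path) -> None:
    payload = {
        "seed": truth.seed,
        "cells": {
            str(k): {
                "archetype": c.archetype,
                "amplitude": c.amplitude,
                "rf_azimuth": c.rf_azimuth,
                "assembly_id": c.assembly_id,
            }
            for k, c in truth.cells.items()
        },
        "assemblies": [
            {
                "assembly_id": a.assembly_id,
                "hemisphere": a.hemisphere,
                "member_roi_ids": a.member_roi_ids,
                "lead_frames": a.lead_frames,
                "event_index": a.event_index,
            }
            for a in truth.assemblies
        ],
        "saccades": [
            {
                "time": e.time,
                "evoked": e.evoked,
                "epoch_index": e.epoch_index,
                "d_left": e.d_left,
                "d_right": e.d_right,
                "azimuth": e.azimuth,
            }
            for e in events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (line 1)")
    return df
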