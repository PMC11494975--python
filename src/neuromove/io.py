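"""Plain-text session interchange: one directory per subject session cell.

Layout (all CSV long/tidy, times in seconds, positions in mm):

    <session_dir>/
        schedule.json      task/rest intervals, cues, cell labels
        skeleton.csv       time + <joint>_{x,y,z} columns (reach cells)
        cursor.csv         time, x, y + geometry in header comment? no:
                           geometry.json holds the circle spec
        od.csv             time, channel, wavelength, value
        eeg.csv            time, channel, value
        ground_truth.json  injected parameters (synthetic sessions only)
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BlockSchedule,
    CircleGeometry,
    CursorTrace,
    EEGRecording,
    RawOptical,
    SkeletonTrace,
)
from . import synthetic

__all__ = ["write_session", "read_session"]


def write_session(session: "synthetic.Session", path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "schedule.json").write_text(json.dumps(session.schedule.to_dict(), indent=1))
    if session.skeleton is not None:
        sk = session.skeleton
        cols = {"time": sk.time}
        for joint, pos in sk.joints.items():
            for i, ax in enumerate("xyz"):
                cols[f"{joint}_{ax}"] = pos[:, i]
        pd.DataFrame(cols).to_csv(path / "skeleton.csv", index=False)
        (path / "skeleton_meta.json").write_text(json.dumps({"side": sk.side}))
    if session.cursor is not None:
        cu = session.cursor
        pd.DataFrame({"time": cu.time, "x": cu.x, "y": cu.y}).to_csv(
            path / "cursor.csv", index=False
        )
        (path / "geometry.json").write_text(json.dumps(asdict(cu.geometry)))
    raw = session.optical
    n, nch, _ = raw.od.shape
    od_rows = pd.DataFrame({
        "time": np.repeat(raw.time, nch * 2),
        "channel": np.tile(np.repeat(raw.channels, 2), n),
        "wavelength": np.tile(list(raw.wavelengths), n * nch),
        "value": raw.od.reshape(-1),
    })
    od_rows.to_csv(path / "od.csv", index=False)
    (path / "od_meta.json").write_text(json.dumps({
        "hemispheres": raw.hemispheres,
        "wavelengths": list(raw.wavelengths),
        "distance_mm": raw.distance_mm,
    }))
    eeg = session.eeg
    pd.DataFrame({
        "time": np.repeat(eeg.time, len(eeg.channels)),
        "channel": np.tile(eeg.channels, len(eeg.time)),
        "value": eeg.data.reshape(-1),
    }).to_csv(path / "eeg.csv", index=False)
    if session.truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(asdict(session.truth), default=float, indent=1)
        )
    return path


def read_session(path: str | Path) -> "synthetic.Session":
    path = Path(path)
    schedule = BlockSchedule.from_dict(json.loads((path / "schedule.json").read_text()))
    skeleton = cursor = None
    if (path / "skeleton.csv").exists():
        df = pd.read_csv(path / "skeleton.csv")
        side = json.loads((path / "skeleton_meta.json").read_text())["side"]
        joints = {}
        for col in df.columns:
            if col.endswith("_x"):
                j = col[:-2]
                joints[j] = df[[f"{j}_x", f"{j}_y", f"{j}_z"]].to_numpy()
        skeleton = SkeletonTrace(df["time"].to_numpy(), joints, side)
    if (path / "cursor.csv").exists():
        df = pd.read_csv(path / "cursor.csv")
        geom = CircleGeometry(**json.loads((path / "geometry.json").read_text()))
        cursor = CursorTrace(df["time"].to_numpy(), df["x"].to_numpy(),
                             df["y"].to_numpy(), geom)
    od_df = pd.read_csv(path / "od.csv")
    meta = json.loads((path / "od_meta.json").read_text())
    channels = list(meta["hemispheres"])
    wavelengths = tuple(meta["wavelengths"])
    times = np.sort(od_df["time"].unique())
    od = np.empty((len(times), len(channels), 2))
    piv = od_df.pivot_table(index="time", columns=["channel", "wavelength"],
                            values="value")
    for j, ch in enumerate(channels):
        for k, wl in enumerate(wavelengths):
            od[:, j, k] = piv[(ch, wl)].to_numpy()
    optical = RawOptical(times, od, channels, meta["hemispheres"],
                         wavelengths, meta["distance_mm"])
    eeg_df = pd.read_csv(path / "eeg.csv")
    ch_order = list(dict.fromkeys(eeg_df["channel"]))
    eegt = np.sort(eeg_df["time"].unique())
    eeg_piv = eeg_df.pivot_table(index="time", columns="channel", values="value")
    eeg = EEGRecording(eegt, eeg_piv[ch_order].to_numpy(), ch_order)
    truth = None
    if (path / "ground_truth.json").exists():
        truth = synthetic.SessionTruth(**json.loads((path / "ground_truth.json").read_text()))
    return synthetic.Session(schedule, skeleton, cursor, optical, eeg, truth)
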