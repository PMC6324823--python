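"""Readers and writers for the delimited-text and image interchange formats.

All tables are UTF-8 comma-delimited with a mandatory header; units are
encoded in column names (``amplitude_pA``, ``time_s``). Movies travel as
multi-frame TIFF with a JSON sidecar carrying acquisition metadata;
puncta images as multi-channel TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import TrialLog
from .events import EventSeries
from .fourier_maps import ResponseMovie
from .minstim import MinStimDataset

__all__ = [
    "read_minstim_table",
    "write_minstim_table",
    "read_events_table",
    "write_events_table",
    "read_trial_log",
    "write_trial_log",
    "read_movie",
    "write_movie",
    "read_puncta_image",
    "write_puncta_image",
]


def _read_csv(path, required: set[str], numeric: set[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - required
    if unknown:
        raise ValueError(f"{path.name}: unknown columns {sorted(unknown)}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = converted
    return df


# --- minimal stimulation ----------------------------------------------------

_MINSTIM_COLS = {
    "cell_id",
    "vh_mv",
    "peak_pA",
    "baseline_rms_pA",
    "series_resistance_mohm",
    "resistance_drift_fraction",
}


def write_minstim_table(ds: MinStimDataset, path) -> None:
    out = ds.trials[["vh_mv", "peak_pA", "baseline_rms_pA"]].copy()
    out.insert(0, "cell_id", ds.cell_id)
    out["series_resistance_mohm"] = ds.qc.get("series_resistance_mohm", np.nan)
    out["resistance_drift_fraction"] = ds.qc.get("resistance_drift_fraction", np.nan)
    out.to_csv(path, index=False)


def read_minstim_table(path) -> list[MinStimDataset]:
    """One table may hold several cells; returns one dataset per cell."""
    df = _read_csv(path, _MINSTIM_COLS, _MINSTIM_COLS - {"cell_id"})
    if len(df) == 0:
        return []
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        qc = {
            "series_resistance_mohm": float(grp["series_resistance_mohm"].iloc[0]),
            "resistance_drift_fraction": float(
                grp["resistance_drift_fraction"].iloc[0]
            ),
        }
        trials = grp[["vh_mv", "peak_pA", "baseline_rms_pA"]].reset_index(drop=True)
        out.append(MinStimDataset(cell_id=str(cell_id), trials=trials, qc=qc))
    return out


# --- event series -----------------------------------------------------------

_EVENT_COLS = {"cell_id", "time_s", "amplitude_pA", "recording_duration_s"}


def write_events_table(series: list[EventSeries], path) -> None:
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": s.cell_id,
                    "time_s": s.times_s,
                    "amplitude_pA": s.amplitudes_pA,
                    "recording_duration_s": s.duration_s,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_events_table(path) -> list[EventSeries]:
    df = _read_csv(path, _EVENT_COLS, _EVENT_COLS - {"cell_id"})
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        out.append(
            EventSeries(
                cell_id=str(cell_id),
                times_s=grp["time_s"].to_numpy(),
                amplitudes_pA=grp["amplitude_pA"].to_numpy(),
                duration_s=float(grp["recording_duration_s"].iloc[0]),
            )
        )
    return out


# --- behavioural trial logs -------------------------------------------------

_TRIAL_COLS = {"task", "phase", "block_id", "level", "correct"}


def write_trial_log(log: TrialLog, path) -> None:
    out = log.trials.copy()
    out.insert(0, "task", log.task)
    out.to_csv(path, index=False)


def read_trial_log(path) -> TrialLog:
    df = _read_csv(path, _TRIAL_COLS, {"block_id", "level"})
    if len(df) == 0:
        raise ValueError(f"{Path(path).name}: empty trial log")
    tasks = df["task"].unique()
    if len(tasks) != 1:
        raise ValueError("trial log mixes tasks")
    df["correct"] = df["correct"].astype(bool)
    return TrialLog(task=str(tasks[0]), trials=df.drop(columns="task"))


# --- movies -----------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: ResponseMovie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "stim_freq_hz": movie.stim_freq_hz,
        "eye": movie.eye,
        "run_id": movie.run_id,
        "n_frames": int(movie.frames.shape[0]),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_movie(path) -> ResponseMovie:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_rate_hz", "stim_freq_hz", "eye"):
        if key not in meta:
            raise ValueError(f"{sidecar.name}: missing metadata field {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim != 3:
        raise ValueError(f"{path.name}: expected a (T, H, W) stack")
    if "n_frames" in meta and frames.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"{path.name}: frame count {frames.shape[0]} does not match "
            f"sidecar ({meta['n_frames']})"
        )
    return ResponseMovie(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        stim_freq_hz=float(meta["stim_freq_hz"]),
        eye=meta["eye"],
        run_id=meta.get("run_id"),
    )


# --- puncta images ----------------------------------------------------------


def write_puncta_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack")


def read_puncta_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 3:
        raise ValueError(f"{Path(path).name}: expected a multi-channel image")
    return np.asarray(img, dtype=float)
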