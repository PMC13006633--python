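"""File formats and configuration.

Formats:

* **Gaze CSV** — one row per 50 Hz sample, columns
  ``participant,group,trial,condition,time_s,x_px,y_px,valid,press_time_s``
  (UTF-8, header required). Dropped samples may be omitted from the file;
  the reader restores the 20-ms grid and marks the gaps invalid. Times
  off the 20-ms grid or non-monotone raise parse errors naming the row.
* **EEG HDF5 container** — either a continuous recording
  (``/data`` channels × samples, ``/channels``, ``/events``, attr ``fs``)
  or an epochs store (``/participants/<id>/epochs``); sample-exact round
  trips, written without HDF5 timestamps so identical content gives
  identical bytes.
* **EDF** (read-only) — through :mod:`mne` when available; channels are
  realigned to the montage by label and onsets come from annotations.
* **YAML pipeline config** — validated strictly (unknown keys rejected).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .eeg import EPOCH_N_SAMPLES, SAMPLING_RATE_HZ, RawRecording
from .gaze import GAZE_DT_S, GazeTrial
from .kinematics import (
    DEFAULT_ANCHOR_PX,
    Condition,
    ScreenGeometry,
    TrajectoryParams,
)
from .montage import MONTAGE_19


class DataError(RuntimeError):
    """Malformed input data (distinct from config validation errors)."""


GAZE_CSV_COLUMNS = (
    "participant", "group", "trial", "condition",
    "time_s", "x_px", "y_px", "valid", "press_time_s",
)


def write_gaze_csv(trials: Sequence[GazeTrial], path) -> None:
    """Write trials in the gaze CSV dialect (one row per sample)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GAZE_CSV_COLUMNS)
        for tr in trials:
            for t, x, y, v in zip(tr.times, tr.x_px, tr.y_px, tr.valid):
                w.writerow(
                    [
                        tr.participant,
                        tr.group,
                        tr.trial_index,
                        tr.condition_label.value,
                        f"{t:.2f}",
                        f"{x:.3f}",
                        f"{y:.3f}",
                        int(v),
                        f"{tr.press_time:.4f}",
                    ]
                )


def read_gaze_csv(path) -> List[GazeTrial]:
    """Read the gaze CSV dialect back into trials.

    Rows of one trial must be time-ordered on the 20-ms grid; missing grid
    times are restored as invalid samples (NaN coordinates).
    """
    groups: Dict[Tuple[str, int], dict] = {}
    order: List[Tuple[str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(GAZE_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DataError(f"gaze CSV missing columns: {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                key = (row["participant"], int(row["trial"]))
                t = float(row["time_s"])
                rec = (
                    t,
                    float(row["x_px"]),
                    float(row["y_px"]),
                    bool(int(row["valid"])),
                )
                press = float(row["press_time_s"])
                cond = Condition(row["condition"])
                grp = row["group"]
            except (KeyError, ValueError) as exc:
                raise DataError(f"gaze CSV row {rownum}: {exc}") from exc
            bin_f = t / GAZE_DT_S
            if abs(bin_f - round(bin_f)) > 1e-6:
                raise DataError(
                    f"gaze CSV row {rownum}: time {t} off the 20-ms grid"
                )
            if key not in groups:
                groups[key] = {
                    "group": grp, "condition": cond, "press": press,
                    "samples": [], "last_t": -math.inf,
                }
                order.append(key)
            g = groups[key]
            if t <= g["last_t"]:
                raise DataError(
                    f"gaze CSV row {rownum}: non-monotone time within trial"
                )
            g["last_t"] = t
            g["samples"].append(rec)

    trials = []
    for key in order:
        g = groups[key]
        bins = [int(round(s[0] / GAZE_DT_S)) for s in g["samples"]]
        n = bins[-1] + 1
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for b, (t, xi, yi, vi) in zip(bins, g["samples"]):
            x[b], y[b], valid[b] = xi, yi, vi
        trials.append(
            GazeTrial(
                times=np.arange(n) * GAZE_DT_S,
                x_px=x, y_px=y, valid=valid,
                press_time=g["press"],
                condition_label=g["condition"],
                participant=key[0],
                group=g["group"],
                trial_index=key[1],
            )
        )
    return trials


# ---------------------------------------------------------------------------
# trajectory parameter table


TRAJECTORY_CSV_COLUMNS = (
    "condition", "initial_speed", "launch_angle", "gravity",
    "duration", "occlusion_onset", "launch_x", "launch_y",
)


def write_trajectory_csv(params: Sequence[TrajectoryParams], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRAJECTORY_CSV_COLUMNS)
        for p in params:
            w.writerow(
                [
                    p.condition_label.value, p.initial_speed, p.launch_angle,
                    p.gravity, p.duration, p.occlusion_onset,
                    p.launch_position[0], p.launch_position[1],
                ]
            )


def read_trajectory_csv(path) -> Dict[Condition, TrajectoryParams]:
    out = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRAJECTORY_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DataError(f"trajectory CSV missing columns: {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                p = TrajectoryParams(
                    condition_label=Condition(row["condition"]),
                    initial_speed=float(row["initial_speed"]),
                    launch_angle=float(row["launch_angle"]),
                    gravity=float(row["gravity"]),
                    duration=float(row["duration"]),
                    occlusion_onset=float(row["occlusion_onset"]),
                    launch_position=(
                        float(row["launch_x"]), float(row["launch_y"]),
                    ),
                )
            except ValueError as exc:
                raise DataError(f"trajectory CSV row {rownum}: {exc}") from exc
            out[p.condition_label] = p
    return out


# ---------------------------------------------------------------------------
# EEG containers


def write_eeg_h5(raw: RawRecording, path) -> None:
    """Sample-exact continuous-recording container."""
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset(
            "data", data=raw.data, track_times=False
        )
        f.create_dataset(
            "channels",
            data=np.array(raw.channel_names, dtype="S"),
            track_times=False,
        )
        f.create_dataset(
            "events", data=np.asarray(raw.events, dtype=float),
            track_times=False,
        )
        f.attrs["fs"] = raw.sfreq


def read_eeg_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        for key in ("data", "channels", "events"):
            if key not in f:
                raise DataError(f"EEG container missing dataset '{key}'")
        channels = tuple(c.decode() for c in f["channels"][()])
        raw = RawRecording(
            channel_names=channels,
            data=f["data"][()],
            sfreq=float(f.attrs["fs"]),
            events=tuple(f["events"][()]),
        )
    if len(raw.events) == 0:
        raise DataError("EEG recording has no stimulus-onset events")
    return raw


def read_eeg_edf(path, montage: Sequence[str] = MONTAGE_19) -> RawRecording:
    """Read an EDF recording, realigning channels to the montage by label.

    Onsets come from EDF annotations. Values are returned in µV. Subject
    to EDF's 16-bit quantization, so round trips through EDF are not
    sample-exact.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise DataError("EDF support requires the optional mne dependency") from exc
    rawmne = mne.io.read_raw_edf(path, preload=True, verbose="error")
    present = {name.strip(): i for i, name in enumerate(rawmne.ch_names)}
    unknown = [name for name in montage if name not in present]
    if unknown:
        raise DataError(f"EDF missing montage channels: {unknown}")
    data = rawmne.get_data(picks=[present[name] for name in montage]) * 1e6
    events = tuple(float(a["onset"]) for a in rawmne.annotations)
    if not events:
        raise DataError("EDF recording has no stimulus-onset events")
    return RawRecording(
        channel_names=tuple(montage),
        data=data,
        sfreq=float(rawmne.info["sfreq"]),
        events=events,
    )


def read_eeg(path) -> RawRecording:
    """Dispatch on extension: ``.edf`` via mne, else the HDF5 container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path)
    return read_eeg_h5(path)


def write_epochs_h5(sessions_epochs: Dict[str, dict], path) -> None:
    """Epochs store: per participant ``epochs`` (n × ch × 2500) + group."""
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset(
            "channels", data=np.array(MONTAGE_19, dtype="S"), track_times=False
        )
        grp = f.create_group("participants", track_order=True)
        for pid in sorted(sessions_epochs):
            entry = sessions_epochs[pid]
            g = grp.create_group(pid, track_order=True)
            g.create_dataset("epochs", data=entry["epochs"], track_times=False)
            g.attrs["group"] = entry["group"]


def read_epochs_h5(path) -> Dict[str, dict]:
    out = {}
    with h5py.File(path, "r") as f:
        for pid in f["participants"]:
            g = f["participants"][pid]
            out[pid] = {
                "epochs": g["epochs"][()],
                "group": g.attrs["group"],
            }
    return out


def write_envelopes_h5(
    participants: Sequence[str],
    groups: Sequence[str],
    envelopes: np.ndarray,
    path,
    *,
    channels: Sequence[str] = MONTAGE_19,
    time_offset_s: float = 0.0,
    fs: float = SAMPLING_RATE_HZ,
) -> None:
    """Participant-mean log-envelope store (participants × ch × samples)."""
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset(
            "envelopes", data=np.asarray(envelopes), track_times=False
        )
        f.create_dataset(
            "participants", data=np.array(list(participants), dtype="S"),
            track_times=False,
        )
        f.create_dataset(
            "groups", data=np.array(list(groups), dtype="S"), track_times=False
        )
        f.create_dataset(
            "channels", data=np.array(list(channels), dtype="S"),
            track_times=False,
        )
        f.attrs["time_offset_s"] = time_offset_s
        f.attrs["fs"] = fs


def read_envelopes_h5(path):
    with h5py.File(path, "r") as f:
        return {
            "envelopes": f["envelopes"][()],
            "participants": [p.decode() for p in f["participants"][()]],
            "groups": [g.decode() for g in f["groups"][()]],
            "channels": [c.decode() for c in f["channels"][()]],
            "time_offset_s": float(f.attrs["time_offset_s"]),
            "fs": float(f.attrs["fs"]),
        }


# ---------------------------------------------------------------------------
# pipeline configuration


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_px: int = 1280
    height_px: int = 1024
    horizontal_extent_deg: float = 35.66
    vertical_extent_deg: float = 28.86
    viewing_distance_cm: float = 60.0
    diagonal_inch: float = 19.0

    def build(self) -> ScreenGeometry:
        return ScreenGeometry(**self.model_dump())


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    artifact_threshold_uv: float = 100.0
    artifact_criterion: str = "absolute"  # or "peak_to_peak"


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    broadband_hz: Tuple[float, float] = (1.0, 40.0)
    lowbeta_hz: Tuple[float, float] = (12.0, 16.0)
    order: int = 4


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    fdr: bool = True
    welch_levene_p: float = 0.10


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 1000
    threshold: float = 0.05
    min_duration_s: float = 0.010
    gap_tolerance_s: float = 0.015
    adjacency_path: Optional[str] = None
    seed: int = 0


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_group_a: int = 6
    n_group_b: int = 11
    trials_per_participant: int = 180
    seed: int = 0
    include_eeg: bool = True
    beta_gain_uv: Optional[float] = None  # None → generator default pattern


class PipelineConfig(BaseModel):
    """Validated top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    anchor_px: Tuple[float, float] = DEFAULT_ANCHOR_PX
    trajectory_table: Optional[str] = None
    qc: QCConfig = Field(default_factory=QCConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    output_dir: str = "gazebeta_out"


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(payload)


def dump_config(config: PipelineConfig, path) -> None:
    """Echo the resolved configuration (omitting the output location, so a
    report bundle's contents depend only on the analysis parameters)."""
    payload = config.model_dump(mode="json", exclude={"output_dir"})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
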