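"""Gaze trial quality control and behavioral prediction metrics.

Behavior in the target-arrival task is summarized by four measures:

* **Position Error (PE) at response** — Euclidean distance, in degrees of
  visual angle, between the gaze position at the button press and the
  target's true landing position.
* **Response Error (RE)** — unsigned difference between the press time and
  the true landing time (4.6 s).
* **Time-series PE** — the same spatial error evaluated at every 20-ms gaze
  sample from motion onset, truncated at the participant's press.
* **Gaze X/Y series** — raw gaze pixel coordinates per 20-ms bin.

Pixel offsets are converted to degrees per axis (the horizontal and
vertical degrees-per-pixel factors differ) before taking the Euclidean
norm. Trials are excluded stepwise: gaze losses (blinks/dropouts between
motion onset and the press) first, then EEG artifact flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kinematics import (
    DEFAULT_ANCHOR_PX,
    Condition,
    ScreenGeometry,
    TrajectoryParams,
    landing_position_px,
    px_to_deg,
)

GAZE_RATE_HZ = 50.0
GAZE_DT_S = 0.02
LANDING_TIME_S = 4.6
#: 20-ms bin grid covering 0.00–4.60 s inclusive.
N_SERIES_BINS = 231
SERIES_TIMES_S = np.round(np.arange(N_SERIES_BINS) * GAZE_DT_S, 10)


class ExclusionReason(str, Enum):
    OK = "ok"
    BLINK_OR_DROPOUT = "blink_or_dropout"
    EEG_ARTIFACT = "eeg_artifact"


@dataclass
class GazeTrial:
    """One trial of 50 Hz gaze samples with a button-press time."""

    times: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    press_time: float
    condition_label: Condition
    participant: str = ""
    group: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.times.size
        if not (self.x_px.size == self.y_px.size == self.valid.size == n):
            raise ValueError("gaze sample arrays must share a length")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or np.any(np.abs(steps - GAZE_DT_S) > 1e-6):
                raise ValueError(
                    "times must increase in 0.02 s steps (mark dropped "
                    "samples invalid instead of omitting rows)"
                )
        if not self.press_time > 0:
            raise ValueError("press_time must be positive")


@dataclass(frozen=True)
class TrialQCResult:
    kept: bool
    reason: ExclusionReason

    def __post_init__(self) -> None:
        if self.kept != (self.reason is ExclusionReason.OK):
            raise ValueError("reason must be 'ok' iff the trial is kept")


def qc_trial(trial: GazeTrial, eeg_artifact_flag: bool = False) -> TrialQCResult:
    """Stepwise trial exclusion: gaze losses first, then EEG artifacts.

    A trial is dropped with reason ``blink_or_dropout`` if any invalid gaze
    sample falls in (0, press_time]; otherwise, with ``eeg_artifact`` if the
    epoch-level flag is set; otherwise it is kept.
    """
    if trial.times.size == 0 or trial.press_time > trial.times[-1] + GAZE_DT_S + 1e-9:
        raise ValueError("press_time lies beyond the recorded gaze samples")
    in_window = (trial.times > 0) & (trial.times <= trial.press_time + 1e-9)
    if np.any(~trial.valid & in_window):
        return TrialQCResult(False, ExclusionReason.BLINK_OR_DROPOUT)
    if eeg_artifact_flag:
        return TrialQCResult(False, ExclusionReason.EEG_ARTIFACT)
    return TrialQCResult(True, ExclusionReason.OK)


def _gaze_at_press(trial: GazeTrial) -> Tuple[float, float]:
    """Latest sample at or before the press (no interpolation: 50 Hz
    sampling and press asynchrony make sub-sample precision spurious)."""
    idx = np.flatnonzero(trial.times <= trial.press_time + 1e-9)
    if idx.size == 0:
        raise ValueError("no gaze sample at or before the button press")
    i = idx[-1]
    return float(trial.x_px[i]), float(trial.y_px[i])


def position_error_deg(
    gaze_px: Tuple[float, float],
    landing_px: Tuple[float, float],
    geometry: ScreenGeometry,
) -> float:
    """Euclidean gaze-to-landing distance in degrees (per-axis conversion
    before the norm)."""
    dx_deg, dy_deg = px_to_deg(
        geometry, gaze_px[0] - landing_px[0], gaze_px[1] - landing_px[1]
    )
    return float(np.hypot(dx_deg, dy_deg))


def position_error_at_response(
    trial: GazeTrial,
    params: TrajectoryParams,
    geometry: ScreenGeometry,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
) -> float:
    """PE at response (degrees of visual angle)."""
    landing = landing_position_px(params, geometry, anchor)
    return position_error_deg(_gaze_at_press(trial), landing, geometry)


def response_error(trial: GazeTrial, landing_time: float = LANDING_TIME_S) -> float:
    """RE: |press_time − landing time| in seconds."""
    return abs(trial.press_time - landing_time)


def pe_time_series(
    trial: GazeTrial,
    params: TrajectoryParams,
    geometry: ScreenGeometry,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
) -> np.ndarray:
    """PE (degrees) against the final landing position per 20-ms bin.

    Length-231 array over 0.00–4.60 s; bins after the press (and bins with
    invalid or missing samples) are NaN.
    """
    lx, ly = landing_position_px(params, geometry, anchor)
    out = np.full(N_SERIES_BINS, np.nan)
    bins = np.rint(trial.times / GAZE_DT_S).astype(int)
    ok = (
        (bins >= 0)
        & (bins < N_SERIES_BINS)
        & trial.valid
        & (trial.times <= trial.press_time + 1e-9)
    )
    dx, dy = px_to_deg(
        geometry, trial.x_px[ok] - lx, trial.y_px[ok] - ly
    )
    out[bins[ok]] = np.hypot(dx, dy)
    return out


def gaze_xy_series(trial: GazeTrial) -> Tuple[np.ndarray, np.ndarray]:
    """Raw gaze X and Y (pixels) per 20-ms bin, truncated at the press."""
    xs = np.full(N_SERIES_BINS, np.nan)
    ys = np.full(N_SERIES_BINS, np.nan)
    bins = np.rint(trial.times / GAZE_DT_S).astype(int)
    ok = (
        (bins >= 0)
        & (bins < N_SERIES_BINS)
        & trial.valid
        & (trial.times <= trial.press_time + 1e-9)
    )
    xs[bins[ok]] = trial.x_px[ok]
    ys[bins[ok]] = trial.y_px[ok]
    return xs, ys


@dataclass
class BehavioralSummary:
    """Per-participant behavioral aggregate over kept trials."""

    participant: str
    group: str
    n_trials: int
    pe_at_response: float
    re: float
    pe_series: np.ndarray
    x_series: np.ndarray
    y_series: np.ndarray
    series_counts: np.ndarray


def participant_aggregate(
    trials: Sequence[GazeTrial],
    params_by_condition,
    geometry: ScreenGeometry,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
) -> BehavioralSummary:
    """Aggregate kept trials of one participant.

    Scalars are plain means; series are pointwise means over the trials
    covering each bin (post-press bins simply drop out of a trial's
    contribution), with the per-bin trial count carried along.
    ``params_by_condition`` maps :class:`Condition` to trajectory params.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("participant has zero kept trials")
    pes = []
    res = []
    pe_stack = np.full((len(trials), N_SERIES_BINS), np.nan)
    x_stack = np.full((len(trials), N_SERIES_BINS), np.nan)
    y_stack = np.full((len(trials), N_SERIES_BINS), np.nan)
    for i, tr in enumerate(trials):
        params = params_by_condition[tr.condition_label]
        pes.append(position_error_at_response(tr, params, geometry, anchor))
        res.append(response_error(tr))
        pe_stack[i] = pe_time_series(tr, params, geometry, anchor)
        x_stack[i], y_stack[i] = gaze_xy_series(tr)
    counts = np.sum(np.isfinite(pe_stack), axis=0)

    def masked_mean(stack: np.ndarray) -> np.ndarray:
        finite = np.isfinite(stack)
        n = finite.sum(axis=0)
        total = np.where(finite, stack, 0.0).sum(axis=0)
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)

    pe_series = masked_mean(pe_stack)
    x_series = masked_mean(x_stack)
    y_series = masked_mean(y_stack)
    return BehavioralSummary(
        participant=trials[0].participant,
        group=trials[0].group,
        n_trials=len(trials),
        pe_at_response=float(np.mean(pes)),
        re=float(np.mean(res)),
        pe_series=pe_series,
        x_series=x_series,
        y_series=y_series,
        series_counts=counts,
    )
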