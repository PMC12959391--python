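"""Drift-injection experiment: repeated routine with pauses, drift throughout.

Reproduces the sweat-drift regime: the wearer repeats a fast multijoint
routine several times with standing pauses in between while drift develops,
starting near the armpits and knees and spreading across the body.  The study
estimates each channel's drift baseline (Savitzky-Golay), its onset time
(first time the baseline rises past 5% of the maximum drift) and the spatial
ordering of onsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body import Skeleton, SkinnedMesh
from .calibration import drift_baseline
from .errors import ContractError
from .motion import ANGLE_RATE, AngleStream, MotionProtocol, Segment, multijoint_routine
from .preprocess import AlignedDataset, resample_linear
from .sensors import DriftModel, SensorParams, SuitDesign, build_drift_field, simulate_stream

ONSET_FRACTION = 0.05


@dataclass
class DriftReport:
    """Per-channel drift baselines, onset estimates and their spatial order."""

    times: np.ndarray
    baselines: np.ndarray  # (F, C) pF
    onset_estimates: np.ndarray  # (C,) s, NaN when no drift detected
    true_onsets: np.ndarray | None = None  # (C,) s from the injected field

    @property
    def onset_order(self) -> np.ndarray:
        """Channels sorted by estimated onset (undetected channels last)."""
        key = np.where(np.isnan(self.onset_estimates), np.inf, self.onset_estimates)
        return np.argsort(key, kind="stable")

    def to_json(self, path) -> None:
        payload = {
            "onset_estimates_s": [None if np.isnan(v) else float(v) for v in self.onset_estimates],
            "onset_order": self.onset_order.tolist(),
        }
        if self.true_onsets is not None:
            payload["true_onsets_s"] = self.true_onsets.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def baselines_to_csv(self, path) -> None:
        df = pd.DataFrame(self.baselines, columns=[f"ch{c:02d}" for c in range(self.baselines.shape[1])])
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)


def drift_schedule_stream(
    routine: AngleStream,
    repetitions: int = 3,
    pause_s: float = 240.0,
    rate: float = ANGLE_RATE,
) -> tuple[AngleStream, MotionProtocol]:
    """Concatenate `repetitions` of the routine with standing pauses between."""
    if repetitions < 1:
        raise ContractError("need at least one repetition")
    blocks = []
    segments = []
    t0 = 0.0
    pause_frames = int(round(pause_s * rate))
    pause = np.zeros((pause_frames, routine.angles.shape[1]))
    for r in range(repetitions):
        blocks.append(routine.angles)
        dur = len(routine.angles) / rate
        segments.append(Segment(t0, t0 + dur, f"routine_{r}", {"repetition": r}))
        t0 += dur
        if r < repetitions - 1:
            blocks.append(pause)
            t0 += pause_frames / rate
    angles = np.vstack(blocks)
    times = np.arange(len(angles)) / rate
    return (
        AngleStream(times=times, angles=angles, dof_names=routine.dof_names),
        MotionProtocol(segments=segments, class_set=[s.label for s in segments]),
    )


def drift_track(values: np.ndarray, rate: float = ANGLE_RATE,
                window_s: float = 45.0) -> np.ndarray:
    """Motion-free drift track per channel via a rolling minimum.

    The capacitive response to motion is non-negative (slack strips clamp at
    zero signal), so the rolling minimum over at least one motion period
    strips the movement content and leaves base capacitance + drift (+ the
    noise floor).  More selective than a smoothing baseline when drift must be
    quantified under activity.
    """
    from scipy.ndimage import minimum_filter1d

    w = max(int(round(window_s * rate)), 1)
    return minimum_filter1d(np.asarray(values, float), size=w, axis=0, mode="nearest")


def estimate_onsets(times: np.ndarray, values: np.ndarray, max_drift: float,
                    fraction: float = ONSET_FRACTION, rate: float = ANGLE_RATE) -> np.ndarray:
    """First time each channel's drift track exceeds `fraction` of max_drift."""
    C = values.shape[1]
    onsets = np.full(C, np.nan)
    if max_drift <= 0:
        return onsets
    track = drift_track(values, rate=rate)
    rel = track - track[0:1, :]
    for c in range(C):
        hit = np.nonzero(rel[:, c] > fraction * max_drift)[0]
        if len(hit):
            onsets[c] = times[hit[0]]
    return onsets


def drift_experiment(
    skeleton: Skeleton,
    design: SuitDesign,
    mesh: SkinnedMesh,
    drift_model: DriftModel,
    routine: AngleStream | None = None,
    repetitions: int = 3,
    pause_s: float = 240.0,
    params: SensorParams | None = None,
    baseline_window: int = 18_000,
    seed: int = 0,
    solver=None,
) -> tuple[AlignedDataset, DriftReport]:
    """Run the repeat-routine-with-pause schedule under an active drift field.

    Returns the aligned (100 Hz) dataset, labels marking the activity blocks,
    and the drift report computed from the Savitzky-Golay baselines.
    """
    params = params or SensorParams(seed=seed)
    if routine is None:
        routine = multijoint_routine(duration=240.0, seed=seed)
    stream, protocol = drift_schedule_stream(routine, repetitions=repetitions, pause_s=pause_s)
    field = build_drift_field(design, skeleton, mesh, drift_model, solver=solver)
    sensor_stream = simulate_stream(skeleton, design, stream, params, drift=field)

    grid, sensors_100 = resample_linear(sensor_stream.times, sensor_stream.values, ANGLE_RATE)
    angles_100 = np.empty((len(grid), stream.angles.shape[1]))
    for d in range(stream.angles.shape[1]):
        angles_100[:, d] = np.interp(grid, stream.times, stream.angles[:, d])

    data = AlignedDataset(
        times=grid,
        sensors=sensors_100,
        angles=angles_100,
        channel_names=list(sensor_stream.channel_names),
        dof_names=list(stream.dof_names),
        labels=protocol.frame_labels(grid),
    )
    baselines = drift_baseline(sensors_100, window=baseline_window)
    onsets = estimate_onsets(grid, sensors_100, drift_model.max_drift)
    report = DriftReport(
        times=grid, baselines=baselines, onset_estimates=onsets, true_onsets=field.onsets
    )
    return data, report
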