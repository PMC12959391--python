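"""Stream conditioning, synchronization, splitting and summary statistics.

Sensor streams arrive at a nominal 40 Hz on their own clock; reference joint
angles arrive at 100 Hz.  The pipeline linearly interpolates sensor values to
100 Hz, optionally low-pass filters the reference angles (4th-order
Butterworth, 10 Hz cutoff, zero-phase), aligns the two clocks on the
deliberate squat bursts recorded at both ends of a session, and splits frames
3:1:1 into train/validation/test either at random (frame level) or
sequentially in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ContractError, DegenerateInputError, SynchronizationError
from .motion import AngleStream, MotionProtocol
from .sensors import SensorStream

SPLIT_RATIO = (3, 1, 1)
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class AlignedDataset:
    """Synchronized sensors + angles on a common 100 Hz clock.

    sensors (F, C) pF; angles (F, D) degrees; labels per-frame class or None;
    split per-frame 'train'/'val'/'test' tags (empty string before splitting).
    """

    times: np.ndarray
    sensors: np.ndarray
    angles: np.ndarray
    channel_names: list[str]
    dof_names: list[str]
    labels: np.ndarray | None = None
    split: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.times)
        if len(self.sensors) != n or len(self.angles) != n:
            raise ContractError("sensors, angles and times must share the frame count")
        if self.labels is not None and len(self.labels) != n:
            raise ContractError("labels must match the frame count")
        if self.split is not None and len(self.split) != n:
            raise ContractError("split tags must match the frame count")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def mask(self, tag: str) -> np.ndarray:
        if self.split is None:
            raise ContractError("dataset has not been split")
        return self.split == tag

    def subset(self, tag: str) -> "AlignedDataset":
        m = self.mask(tag)
        return AlignedDataset(
            times=self.times[m],
            sensors=self.sensors[m],
            angles=self.angles[m],
            channel_names=self.channel_names,
            dof_names=self.dof_names,
            labels=None if self.labels is None else self.labels[m],
            split=self.split[m],
        )

    # -- disk round trip (directory of CSVs + manifest) ----------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.sensors, columns=self.channel_names).assign(time_s=self.times).to_csv(
            path / "sensors.csv", index=False
        )
        pd.DataFrame(self.angles, columns=self.dof_names).assign(time_s=self.times).to_csv(
            path / "angles.csv", index=False
        )
        if self.labels is not None:
            pd.DataFrame({"label": self.labels}).to_csv(path / "labels.csv", index=False)
        if self.split is not None:
            pd.DataFrame({"split": self.split}).to_csv(path / "split.csv", index=False)
        manifest = {
            "n_frames": int(self.n_frames),
            "channels": self.channel_names,
            "dofs": self.dof_names,
            "has_labels": self.labels is not None,
            "has_split": self.split is not None,
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def from_dir(cls, path) -> "AlignedDataset":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        sensors = pd.read_csv(path / "sensors.csv")
        angles = pd.read_csv(path / "angles.csv")
        labels = split = None
        if manifest["has_labels"]:
            labels = pd.read_csv(path / "labels.csv")["label"].to_numpy(dtype=object)
        if manifest["has_split"]:
            split = pd.read_csv(path / "split.csv")["split"].to_numpy(dtype=object)
        return cls(
            times=sensors["time_s"].to_numpy(),
            sensors=sensors[manifest["channels"]].to_numpy(),
            angles=angles[manifest["dofs"]].to_numpy(),
            channel_names=manifest["channels"],
            dof_names=manifest["dofs"],
            labels=labels,
            split=split,
        )


# ---------------------------------------------------------------------------
# resampling & filtering


def resample_linear(times: np.ndarray, values: np.ndarray, target_rate: float = 100.0):
    """Linear interpolation onto a uniform grid spanning [t0, tN].

    Endpoint values are preserved and outputs never exceed the local input
    envelope (linear interpolation is monotone between knots).
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    if len(times) < 2:
        raise ContractError("need at least two frames to resample")
    if np.any(np.diff(times) <= 0):
        raise ContractError("times must be strictly increasing")
    n = int(np.floor((times[-1] - times[0]) * target_rate)) + 1
    grid = times[0] + np.arange(n) / target_rate
    out = np.empty((n, values.shape[1]))
    for c in range(values.shape[1]):
        out[:, c] = np.interp(grid, times, values[:, c])
    return grid, out


def lowpass_reference(angles: np.ndarray, rate: float = 100.0, order: int = 4,
                      cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass of reference angles (marker-vibration removal)."""
    if rate <= 2 * cutoff:
        raise ContractError(f"rate {rate} Hz too low for a {cutoff} Hz cutoff")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(angles, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# squat-peak synchronization


def _edge_peak_trains(t: np.ndarray, x: np.ndarray, prominence: float):
    """The bursts of prominent peaks at the very start and end of a series.

    A train is the maximal prefix (suffix) of peaks whose consecutive gaps
    stay within 2x the leading (trailing) gap — the deliberate squat bursts
    bracket the recording, so the protocol's own peaks in the middle never
    join them.  Returns (first_train_times, last_train_times) or None.
    """
    peaks, _ = signal.find_peaks(x, prominence=prominence)
    if len(peaks) < 2:
        return None
    pt = t[peaks]
    gaps = np.diff(pt)
    k = 1
    while k < len(gaps) and gaps[k] <= 2.0 * gaps[0]:
        k += 1
    first = pt[: k + 1]
    k = len(gaps) - 2
    while k >= 0 and gaps[k] <= 2.0 * gaps[-1]:
        k -= 1
    last = pt[k + 2:]
    return first, last


def _coarse_offset_xcorr(sensors: SensorStream, knee_chan: int,
                         angle_times: np.ndarray, knee_angle: np.ndarray) -> float:
    """Coarse clock offset (angle time minus sensor time) by cross-correlation.

    Both knee-band signals are resampled to the sensor rate and standardized;
    the full FFT cross-correlation peak gives the offset to one sensor frame.
    """
    dt = float(np.median(np.diff(sensors.times)))
    grid_a = np.arange(angle_times[0], angle_times[-1] + 1e-9, dt)
    a = np.interp(grid_a, angle_times, knee_angle)
    s = sensors.values[:, knee_chan]
    a = (a - a.mean()) / (a.std() + 1e-12)
    s = (s - s.mean()) / (s.std() + 1e-12)
    corr = signal.correlate(a, s, mode="full", method="fft")
    lag = np.argmax(corr) - (len(s) - 1)
    return float(grid_a[0] - sensors.times[0] + lag * dt)


def estimate_clock_map(
    sensors: SensorStream,
    angles: AngleStream,
    knee_channel: int | None = None,
    knee_dofs: tuple[str, ...] = ("LK_X", "RK_X"),
    angle_prominence: float = 60.0,
) -> dict:
    """Clock offset and scale between sensor and angle streams from squat trains.

    Returns {'offset': angle-time minus sensor-time at the first train,
    'scale': angle seconds per sensor second, 'anchor_angle', 'anchor_sensor',
    'channel': the knee channel used}.
    """
    kd = [angles.dof_names.index(d) for d in knee_dofs if d in angles.dof_names]
    if not kd:
        raise SynchronizationError("no knee DoF in the angle stream")
    knee_angle = angles.angles[:, kd].max(axis=1)
    ref = _edge_peak_trains(angles.times, knee_angle, prominence=angle_prominence)
    if ref is None:
        raise SynchronizationError(
            "no squat peaks found in the angle stream",
            {"prominence": angle_prominence},
        )
    if knee_channel is None:
        # channel with the strongest response correlated to the knee angle
        # (coarse: assumes the clocks are within the stream span of each other)
        knee_on_sensor_clock = np.interp(sensors.times, angles.times, knee_angle)
        x = sensors.values - sensors.values.mean(axis=0, keepdims=True)
        k = knee_on_sensor_clock - knee_on_sensor_clock.mean()
        with np.errstate(invalid="ignore"):
            corr = np.abs(x.T @ k) / (np.linalg.norm(x, axis=0) * np.linalg.norm(k) + 1e-12)
        knee_channel = int(np.nanargmax(corr))
    chan = sensors.values[:, knee_channel]
    swing = np.percentile(chan, 98) - np.percentile(chan, 2)
    sen = _edge_peak_trains(sensors.times, chan, prominence=0.3 * swing)
    if sen is None:
        raise SynchronizationError(
            "no squat peaks found in the sensor stream",
            {"channel": knee_channel},
        )
    coarse = _coarse_offset_xcorr(sensors, knee_channel, angles.times, knee_angle)

    def _local_offset(train_times: np.ndarray, pad: float = 3.0,
                      rate: float = 200.0, max_lag: float = 1.5) -> float | None:
        """Sub-frame offset near one squat train by windowed cross-correlation."""
        w0, w1 = train_times[0] - pad, train_times[-1] + pad
        t = np.arange(w0, w1, 1.0 / rate)
        a = np.interp(t, angles.times, knee_angle)
        s = np.interp(t, sensors.times + coarse, sensors.values[:, knee_channel])
        a = a - a.mean()
        s = s - s.mean()
        corr = signal.correlate(a, s, mode="full", method="fft")
        lags = np.arange(-len(t) + 1, len(t))
        ok = np.abs(lags) <= max_lag * rate
        if not ok.any():
            return None
        sub = corr[ok]
        k = int(np.argmax(sub))
        # parabolic interpolation around the correlation peak
        if 0 < k < len(sub) - 1:
            y0, y1, y2 = sub[k - 1], sub[k], sub[k + 1]
            denom = y0 - 2 * y1 + y2
            frac = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        else:
            frac = 0.0
        return coarse + (lags[ok][k] + frac) / rate

    a_first, a_last = float(np.mean(ref[0])), float(np.mean(ref[1]))
    o_first = _local_offset(ref[0])
    o_last = _local_offset(ref[1])
    if o_first is None or o_last is None:
        raise SynchronizationError(
            "squat trains do not match between streams",
            {"coarse_offset": coarse, "channel": knee_channel},
        )
    # sensor-clock anchors of the two trains, then a linear clock map
    s_first = a_first - o_first
    s_last = a_last - o_last
    if abs(s_last - s_first) > 1e-9 and abs(a_last - a_first) > 1e-9:
        scale = (a_last - a_first) / (s_last - s_first)
    else:
        scale = 1.0
    return {
        "offset": o_first,
        "scale": scale,
        "anchor_angle": a_first,
        "anchor_sensor": s_first,
        "channel": knee_channel,
        "coarse_offset": coarse,
    }


def synchronize_streams(
    sensors: SensorStream,
    angles: AngleStream,
    knee_channel: int | None = None,
    knee_dofs: tuple[str, ...] = ("LK_X", "RK_X"),
    angle_prominence: float = 60.0,
    target_rate: float = 100.0,
) -> AlignedDataset:
    """Align a sensor stream to the angle clock via the squat bursts.

    Replaces the visual peak-matching step: squat trains are detected in a
    knee DoF and in a knee-associated sensor channel; the offsets of the
    first trains give the clock shift and the first-vs-last train pair gives
    a linear clock scale.  The sensor stream is then remapped to the angle
    clock and resampled to ``target_rate``.
    """
    cmap = estimate_clock_map(
        sensors, angles, knee_channel=knee_channel, knee_dofs=knee_dofs,
        angle_prominence=angle_prominence,
    )
    mapped_times = cmap["anchor_angle"] + (sensors.times - cmap["anchor_sensor"]) * cmap["scale"]

    grid, sens_values = resample_linear(mapped_times, sensors.values, target_rate)
    # crop to the overlap of both streams and sample angles on the same grid
    lo = max(grid[0], angles.times[0])
    hi = min(grid[-1], angles.times[-1])
    keep = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    grid = grid[keep]
    sens_values = sens_values[keep]
    ang_values = np.empty((len(grid), angles.angles.shape[1]))
    for d in range(angles.angles.shape[1]):
        ang_values[:, d] = np.interp(grid, angles.times, angles.angles[:, d])

    return AlignedDataset(
        times=grid,
        sensors=sens_values,
        angles=ang_values,
        channel_names=list(sensors.channel_names),
        dof_names=list(angles.dof_names),
    )


def align_streams_shared_clock(
    sensors: SensorStream,
    angles: AngleStream,
    target_rate: float = 100.0,
) -> AlignedDataset:
    """Align two streams that already share a clock (no squat matching):
    interpolate sensors to ``target_rate`` and sample angles on the same grid."""
    grid, sens_values = resample_linear(sensors.times, sensors.values, target_rate)
    keep = grid <= angles.times[-1] + 1e-9
    grid, sens_values = grid[keep], sens_values[keep]
    ang_values = np.empty((len(grid), angles.angles.shape[1]))
    for d in range(angles.angles.shape[1]):
        ang_values[:, d] = np.interp(grid, angles.times, angles.angles[:, d])
    return AlignedDataset(
        times=grid,
        sensors=sens_values,
        angles=ang_values,
        channel_names=list(sensors.channel_names),
        dof_names=list(angles.dof_names),
    )


def attach_labels(dataset: AlignedDataset, protocol: MotionProtocol) -> AlignedDataset:
    """Per-frame class labels from the protocol's segments."""
    dataset.labels = protocol.frame_labels(dataset.times)
    return dataset


def crop_to_protocol(dataset: AlignedDataset, protocol: MotionProtocol) -> AlignedDataset:
    """Keep only frames within the protocol span (drops the sync squat bursts,
    which are alignment artifacts rather than analysis data)."""
    t0 = protocol.segments[0].start_s
    t1 = protocol.segments[-1].end_s
    m = (dataset.times >= t0 - 1e-9) & (dataset.times < t1 - 1e-9)
    return AlignedDataset(
        times=dataset.times[m],
        sensors=dataset.sensors[m],
        angles=dataset.angles[m],
        channel_names=dataset.channel_names,
        dof_names=dataset.dof_names,
        labels=None if dataset.labels is None else dataset.labels[m],
        split=None if dataset.split is None else dataset.split[m],
    )


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    dataset: AlignedDataset,
    mode: str = "random",
    ratio: tuple[int, int, int] = SPLIT_RATIO,
    seed: int = 0,
) -> AlignedDataset:
    """Assign train/val/test tags at the frame level.

    random     -- seeded frame permutation (matches a random 3:1:1 split)
    sequential -- contiguous blocks in time order
    sequential_by_class -- sequential 3:1:1 within each labeled class (the
                  discipline for sequence-classification experiments, where
                  each class's recording is split along its own timeline)
    """
    n = dataset.n_frames
    if n < 5:
        raise ContractError("need at least 5 frames to split 3:1:1")
    tags = np.empty(n, dtype=object)

    def assign_block(indices: np.ndarray) -> np.ndarray:
        m = len(indices)
        total = sum(ratio)
        n_val = m * ratio[1] // total
        n_test = m * ratio[2] // total
        n_train = m - n_val - n_test  # remainder goes to train
        out = np.empty(m, dtype=object)
        out[:n_train] = "train"
        out[n_train: n_train + n_val] = "val"
        out[n_train + n_val:] = "test"
        return out

    if mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        tags[perm] = assign_block(perm)
    elif mode == "sequential":
        tags[:] = assign_block(np.arange(n))
    elif mode == "sequential_by_class":
        if dataset.labels is None:
            raise ContractError("sequential_by_class requires labels")
        tags[:] = ""
        for cls in pd.unique(dataset.labels[dataset.labels != None]):  # noqa: E711
            idx = np.nonzero(dataset.labels == cls)[0]
            tags[idx] = assign_block(idx)
        tags[tags == ""] = "train"  # unlabeled frames never reach evaluation
    else:
        raise ContractError(f"unknown split mode {mode!r}")

    dataset.split = tags
    return dataset


# ---------------------------------------------------------------------------
# summary statistics


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) per column; errors on constant input."""
    x = np.asarray(series, dtype=float)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    if np.any(hi - lo <= 0):
        raise DegenerateInputError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def summed_angle_change_rate(angles: AngleStream | np.ndarray) -> tuple[np.ndarray, float]:
    """Total absolute angular change of all DoFs per 10-ms frame.

    Returns the per-frame series (deg / 10 ms, length F-1) and its mean, the
    stream's motion-complexity statistic.
    """
    table = angles.angles if isinstance(angles, AngleStream) else np.asarray(angles, float)
    series = np.abs(np.diff(table, axis=0)).sum(axis=1)
    return series, float(series.mean()) if len(series) else 0.0
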