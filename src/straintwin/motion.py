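"""Scripted, labeled synthetic motion protocols.

These generators stand in for the human data-collection regimes of a suit
study: a large daily-pose corpus (range statistics), single-joint sweep
protocols over 11 joints x 3 axes, a fast multijoint calisthenics-like
routine, periodic pick-and-place reaches (3 heights x 5 speeds, metronome at
90 BPM for 1.0x) and treadmill gait (speeds / step widths / slopes).  Every
generator is seeded and deterministic, emits ground-truth joint angles at
100 Hz in degrees, and labels 1-min class segments.

Each labeled class is treated as a separate recording session: a small random
baseline-posture offset (default sd 3 deg) is drawn per class, emulating the
shift of the stationary pose offset when a garment is re-donned between
recordings.  Frequency-domain analyses of real suit data remove exactly such
a per-recording stationary offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .body import AXES, JOINT_ORDER, PROTOCOL_JOINT_ORDER
from .errors import ConfigurationError, ContractError

ANGLE_RATE = 100.0  # Hz of ground-truth angle streams

#: Default movement ranges (degrees) used by all generators; realistic
#: physiological magnitudes on the capsule body's axis conventions (arms along
#: +/-X in the rest pose, legs along -Y; intrinsic XYZ Euler angles).
DEFAULT_JOINT_RANGES: dict[str, tuple[float, float]] = {}
_RANGE_TABLE = {
    "LE": {"X": (-45, 45), "Y": (0, 135), "Z": (-20, 20)},
    "RE": {"X": (-45, 45), "Y": (-135, 0), "Z": (-20, 20)},
    "LS": {"X": (-60, 60), "Y": (-70, 70), "Z": (-80, 40)},
    "RS": {"X": (-60, 60), "Y": (-70, 70), "Z": (-40, 80)},
    "LC": {"X": (-15, 15), "Y": (-15, 15), "Z": (-15, 15)},
    "RC": {"X": (-15, 15), "Y": (-15, 15), "Z": (-15, 15)},
    "UB": {"X": (-20, 40), "Y": (-25, 25), "Z": (-20, 20)},
    "LB": {"X": (-25, 45), "Y": (-30, 30), "Z": (-20, 20)},
    "T": {"X": (-30, 45), "Y": (-45, 45), "Z": (-25, 25)},
    "LT": {"X": (-25, 95), "Y": (-30, 30), "Z": (-20, 45)},
    "RT": {"X": (-25, 95), "Y": (-30, 30), "Z": (-45, 20)},
    "LK": {"X": (0, 130), "Y": (-10, 10), "Z": (-8, 8)},
    "RK": {"X": (0, 130), "Y": (-10, 10), "Z": (-8, 8)},
}
for _j in JOINT_ORDER:
    for _ax in AXES:
        DEFAULT_JOINT_RANGES[f"{_j}_{_ax}"] = tuple(map(float, _RANGE_TABLE[_j][_ax]))

DOF_NAMES = [f"{j}_{ax}" for j in JOINT_ORDER for ax in AXES]


@dataclass
class AngleStream:
    """Ground-truth joint angles: times (s) at a nominal 100 Hz, degrees."""

    times: np.ndarray
    angles: np.ndarray  # (frames, 39)
    dof_names: list[str] = field(default_factory=lambda: list(DOF_NAMES))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (len(self.times), len(self.dof_names)):
            raise ContractError("angle table shape must be (frames, n_dof)")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times))) if len(self.times) > 1 else np.nan

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=self.dof_names)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AngleStream":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ContractError("angle CSV must contain a time_s column")
        names = [c for c in df.columns if c != "time_s"]
        return cls(times=df["time_s"].to_numpy(), angles=df[names].to_numpy(), dof_names=names)


@dataclass
class Segment:
    start_s: float
    end_s: float
    label: str
    meta: dict = field(default_factory=dict)


@dataclass
class MotionProtocol:
    """Ordered, non-overlapping labeled segments over a stream."""

    segments: list[Segment]
    class_set: list[str]

    def __post_init__(self):
        prev_end = -np.inf
        for seg in self.segments:
            if seg.start_s < prev_end - 1e-9 or seg.end_s <= seg.start_s:
                raise ContractError("protocol segments must be ordered and non-overlapping")
            prev_end = seg.end_s

    def frame_labels(self, times: np.ndarray) -> np.ndarray:
        """Per-frame class label; None outside all segments."""
        labels = np.full(len(times), None, dtype=object)
        for seg in self.segments:
            mask = (times >= seg.start_s - 1e-9) & (times < seg.end_s - 1e-9)
            labels[mask] = seg.label
        return labels

    def shifted(self, dt: float) -> "MotionProtocol":
        return MotionProtocol(
            segments=[Segment(s.start_s + dt, s.end_s + dt, s.label, dict(s.meta)) for s in self.segments],
            class_set=list(self.class_set),
        )

    def to_json_dict(self) -> dict:
        return {
            "class_set": self.class_set,
            "segments": [
                {"start_s": s.start_s, "end_s": s.end_s, "label": s.label, "meta": s.meta}
                for s in self.segments
            ],
        }


def _clip_to_ranges(angles: np.ndarray, ranges: dict, dof_names=DOF_NAMES) -> np.ndarray:
    lo = np.array([ranges.get(n, (-180.0, 180.0))[0] for n in dof_names])
    hi = np.array([ranges.get(n, (-180.0, 180.0))[1] for n in dof_names])
    return np.clip(angles, lo, hi)


# ---------------------------------------------------------------------------
# daily-pose corpus


def sample_pose_corpus(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 10000,
    seed: int = 0,
    dof_names: list[str] | None = None,
) -> pd.DataFrame:
    """Synthetic daily-pose corpus: per-DoF truncated normals within ranges.

    Stands in for a large mocap pose archive when computing movement-range
    histograms.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ContractError("corpus size must be >= 1")
    ranges = dict(DEFAULT_JOINT_RANGES if ranges is None else ranges)
    dof_names = dof_names or list(ranges.keys())
    rng = np.random.default_rng(seed)
    cols = {}
    for name in dof_names:
        lo, hi = ranges[name]
        mid, sd = 0.5 * (lo + hi), max((hi - lo) / 4.0, 1e-9)
        a, b = (lo - mid) / sd, (hi - mid) / sd
        cols[name] = stats.truncnorm.rvs(a, b, loc=mid, scale=sd, size=n, random_state=rng)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# background jitter shared by protocols


def _smooth_jitter(rng, n_frames: int, n_dof: int, rate: float, amp: float) -> np.ndarray:
    """Slow, smooth random wander per DoF (sum of two low-frequency sinusoids)."""
    t = np.arange(n_frames) / rate
    freqs = rng.uniform(0.05, 0.3, size=(2, n_dof))
    phases = rng.uniform(0, 2 * np.pi, size=(2, n_dof))
    amps = rng.uniform(0.3, 1.0, size=(2, n_dof)) * amp / 2
    out = np.zeros((n_frames, n_dof))
    for k in range(2):
        out += amps[k] * np.sin(2 * np.pi * freqs[k][None, :] * t[:, None] + phases[k][None, :])
    return out


# ---------------------------------------------------------------------------
# single-joint sweep protocol


def single_joint_protocol(
    ranges: dict[str, tuple[float, float]] | None = None,
    reps: int = 5,
    seed: int = 0,
    segment_s: float | None = None,
    rate: float = ANGLE_RATE,
    jitter_deg: float = 2.0,
) -> tuple[AngleStream, MotionProtocol]:
    """Single-joint sweeps: 11 joints x 3 axes, `reps` sweeps per segment.

    Follows the joint order LE, LS, RE, RS, UB, LB, T, LT, RT, LK, RK with
    axes X, Y, Z in serial.  The default timing yields 387 s total (38,700
    frames at 100 Hz).  Other joints carry a small seeded wander (a wearer
    cannot keep them perfectly still).
    """
    ranges = dict(DEFAULT_JOINT_RANGES if ranges is None else ranges)
    joints = [j for j in PROTOCOL_JOINT_ORDER]
    n_segments = len(joints) * len(AXES)
    if segment_s is None:
        segment_s = 387.0 / n_segments
    n_frames = int(round(segment_s * n_segments * rate))
    bounds = np.round(np.linspace(0, n_frames, n_segments + 1)).astype(int)
    t = np.arange(n_frames) / rate

    rng = np.random.default_rng(seed)
    angles = _smooth_jitter(rng, n_frames, len(DOF_NAMES), rate, jitter_deg)

    segments = []
    for si, (joint, axis) in enumerate((j, ax) for j in joints for ax in AXES):
        name = f"{joint}_{axis}"
        lo, hi = ranges[name]
        d = DOF_NAMES.index(name)
        i0, i1 = bounds[si], bounds[si + 1]
        u = np.arange(i1 - i0) / (i1 - i0)
        # positive half-waves reach hi, negative half-waves reach lo; the
        # trajectory starts and ends at the rest angle, giving `reps` peaks
        wave = np.sin(2 * np.pi * reps * u)
        traj = hi * np.clip(wave, 0, None) + lo * np.clip(-wave, 0, None)
        angles[i0:i1, d] = traj
        segments.append(Segment(i0 / rate, i1 / rate, name, {"joint": joint, "axis": axis}))

    angles = _clip_to_ranges(angles, ranges)
    stream = AngleStream(times=t, angles=angles)
    proto = MotionProtocol(segments=segments, class_set=[s.label for s in segments])
    return stream, proto


# ---------------------------------------------------------------------------
# multijoint calisthenics-like routine


def multijoint_routine(
    duration: float = 240.0,
    target_rate: float = 15.9,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    rate: float = ANGLE_RATE,
    n_exercises: int = 8,
    ramp_s: float = 0.5,
) -> AngleStream:
    """Fast whole-body choreographed routine (calisthenics-like).

    The routine is a sequence of rhythmic exercises.  Within an exercise every
    active DoF oscillates at the exercise's beat frequency (or its first
    harmonic) with a quantized phase — the whole body moves as one periodic
    synergy, as in a scripted warm-up routine.  Amplitudes are scaled so the
    mean summed angle-change rate (total absolute angular change of all DoFs
    per 10 ms) matches ``target_rate``; amplitude envelopes ramp in and out at
    exercise boundaries so angles stay continuous.  Raises ConfigurationError
    when the target is unreachable within the movement ranges.
    """
    if duration <= 0:
        raise ContractError("duration must be positive")
    ranges = dict(DEFAULT_JOINT_RANGES if ranges is None else ranges)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * rate))
    t = np.arange(n_frames) / rate
    D = len(DOF_NAMES)

    spans = np.array([ranges[n][1] - ranges[n][0] for n in DOF_NAMES])
    mids = np.array([0.5 * (ranges[n][0] + ranges[n][1]) for n in DOF_NAMES])

    if target_rate == 0:
        return AngleStream(times=t, angles=np.tile(mids, (n_frames, 1)))

    ex_frames = n_frames // n_exercises
    beats = rng.uniform(0.5, 1.0, size=n_exercises)
    harmonics = rng.choice([1, 1, 1, 2], size=(n_exercises, D))
    phases = rng.choice([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], size=(n_exercises, D))
    # each exercise strongly activates a subset of DoFs, the rest move gently
    activation = np.where(rng.random((n_exercises, D)) < 0.4, 1.0, 0.15)
    base_amp = activation * (spans / 4.0) * rng.uniform(0.6, 1.0, size=(n_exercises, D))

    # mean |d angle| per 10 ms of A sin(2 pi f t) is A * f * 0.04 deg; the
    # ramps to/from the neutral stance contribute 2 * sum|mid| per exercise
    ramp_rate = 2.0 * n_exercises * float(np.sum(np.abs(mids))) / n_frames
    osc_target = target_rate - ramp_rate
    if osc_target <= 0:
        raise ConfigurationError(
            f"target rate {target_rate} deg/10ms below the posture-transition floor "
            f"({ramp_rate:.2f})"
        )
    f_eff = beats[:, None] * harmonics
    analytic = float(np.mean(np.sum(base_amp * f_eff * 0.04, axis=1)))
    max_rate = float(np.mean(np.sum((spans / 2.0) * f_eff * 0.04, axis=1))) + ramp_rate
    if target_rate > max_rate:
        raise ConfigurationError(
            f"target rate {target_rate} deg/10ms unreachable (max {max_rate:.1f})"
        )
    amps = np.minimum(base_amp * (osc_target / analytic), spans / 2.0)
    analytic2 = float(np.mean(np.sum(amps * f_eff * 0.04, axis=1)))
    amps = np.minimum(amps * (osc_target / analytic2), spans / 2.0)

    # the envelope ramps the whole exercise pose (offset + oscillation) in and
    # out, so the body passes through the neutral standing pose between
    # exercises, as in a scripted warm-up routine
    angles = np.zeros((n_frames, D))
    ramp_frames = max(int(round(ramp_s * rate)), 1)
    for e in range(n_exercises):
        i0 = e * ex_frames
        i1 = n_frames if e == n_exercises - 1 else (e + 1) * ex_frames
        tt = t[i0:i1] - t[i0]
        env = np.ones(i1 - i0)
        env[:ramp_frames] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_frames) / ramp_frames))
        env[-ramp_frames:] *= 0.5 * (1 + np.cos(np.pi * np.arange(ramp_frames) / ramp_frames))
        wave = np.sin(
            2 * np.pi * beats[e] * harmonics[e][None, :] * tt[:, None] + phases[e][None, :]
        )
        angles[i0:i1] = env[:, None] * (mids[None, :] + amps[e][None, :] * wave)
    return AngleStream(times=t, angles=_clip_to_ranges(angles, ranges))


# ---------------------------------------------------------------------------
# pick-and-place reaches


_HEIGHT_AMPLITUDES = {
    # (shoulder amplitude, elbow amplitude): the wearer uses shoulders more
    # for upper reaches, elbows predominantly for middle, elbows slightly
    # more than shoulders for lower reaches.
    "upper": (55.0, 25.0),
    "middle": (12.0, 65.0),
    "lower": (30.0, 40.0),
}


def pick_place_protocol(
    heights: tuple[str, ...] = ("upper", "middle", "lower"),
    speeds: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2, 1.4),
    bpm_base: float = 90.0,
    segment_s: float = 60.0,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    rate: float = ANGLE_RATE,
    session_offset_sd: float = 3.0,
) -> tuple[AngleStream, MotionProtocol]:
    """Periodic left/right reaches at height x speed classes (default 15).

    One reach half-cycle per metronome beat, so the reach frequency of a
    class is speed x (bpm/60) / 2 Hz.
    """
    ranges = dict(DEFAULT_JOINT_RANGES if ranges is None else ranges)
    for h in heights:
        if h not in _HEIGHT_AMPLITUDES:
            raise ConfigurationError(f"unknown height level {h!r}")
    rng = np.random.default_rng(seed)
    classes = [(h, s) for h in heights for s in speeds]
    seg_frames = int(round(segment_s * rate))
    n_frames = seg_frames * len(classes)
    t = np.arange(n_frames) / rate
    angles = _smooth_jitter(rng, n_frames, len(DOF_NAMES), rate, 1.0)

    segments = []
    for ci, (height, speed) in enumerate(classes):
        label = f"{height}_{speed:g}x"
        i0, i1 = ci * seg_frames, (ci + 1) * seg_frames
        tt = np.arange(seg_frames) / rate
        f = speed * (bpm_base / 60.0) / 2.0
        sh_amp, el_amp = _HEIGHT_AMPLITUDES[height]
        phase = rng.uniform(0, 2 * np.pi)
        wave_l = np.sin(2 * np.pi * f * tt + phase)
        wave_r = np.sin(2 * np.pi * f * tt + phase + np.pi)
        offset = rng.normal(0.0, session_offset_sd, size=len(DOF_NAMES))

        block = np.zeros((seg_frames, len(DOF_NAMES)))

        def put(name, traj):
            block[:, DOF_NAMES.index(name)] += traj

        put("LS_Y", sh_amp * 0.8 * wave_l)
        put("RS_Y", sh_amp * 0.8 * wave_r)
        put("LS_Z", -sh_amp * 0.5 * np.clip(wave_l, 0, None))
        put("RS_Z", sh_amp * 0.5 * np.clip(wave_r, 0, None))
        put("LE_Y", el_amp * 0.5 * (1 + wave_l) / 1.0)
        put("RE_Y", -el_amp * 0.5 * (1 + wave_r))
        put("T_Y", 8.0 * wave_l)
        angles[i0:i1] += block + offset[None, :]
        segments.append(Segment(i0 / rate, i1 / rate, label, {"height": height, "speed": speed}))

    angles = _clip_to_ranges(angles, ranges)
    stream = AngleStream(times=t, angles=angles)
    proto = MotionProtocol(segments=segments, class_set=[s.label for s in segments])
    return stream, proto


# ---------------------------------------------------------------------------
# treadmill gait


_WIDTH_ABDUCTION = {  # hip ab/adduction amplitude per step-width class, deg
    "narrow-": 2.0,
    "narrow": 5.0,
    "regular": 9.0,
    "wide": 15.0,
    "sway": 22.0,
}


def _gait_class_table(speeds, widths, slopes) -> list[dict]:
    classes = [
        {"label": f"speed_{s:g}x", "speed": s, "width": "regular", "slope": 0.0}
        for s in speeds
    ]
    classes += [
        {"label": f"width_{w}", "speed": 1.0, "width": w, "slope": 0.0} for w in widths
    ]
    classes += [
        {"label": f"slope_{d:g}", "speed": 1.0, "width": "regular", "slope": float(d)}
        for d in slopes
    ]
    return classes


def gait_protocol(
    speeds: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2),
    widths: tuple[str, ...] = ("narrow-", "narrow", "regular", "wide", "sway"),
    slopes: tuple[float, ...] = (-6.0, -3.0, 0.0, 3.0, 6.0, 9.0),
    segment_s: float = 60.0,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    rate: float = ANGLE_RATE,
    base_cadence: float = 0.9,
    session_offset_sd: float = 3.0,
    hip_amp: float = 25.0,
    knee_amp: float = 45.0,
    amplitude_scale: float = 1.0,
    jitter_deg: float = 1.0,
) -> tuple[AngleStream, MotionProtocol]:
    """Treadmill gait classes: speeds + step widths + slopes (default 15 labels).

    Cadence scales with the speed multiplier; width classes redistribute hip
    ab/adduction amplitude; inclines raise hip flexion and lower knee
    amplitude, declines the reverse.  Left/right legs run in antiphase.  The
    baseline condition (1.0x, regular, 0 deg) appears once per group under a
    distinct label, as in the source protocols where each class was its own
    recording.
    """
    ranges = dict(DEFAULT_JOINT_RANGES if ranges is None else ranges)
    for w in widths:
        if w not in _WIDTH_ABDUCTION:
            raise ConfigurationError(f"unknown step width {w!r}")
    rng = np.random.default_rng(seed)
    classes = _gait_class_table(speeds, widths, slopes)
    seg_frames = int(round(segment_s * rate))
    n_frames = seg_frames * len(classes)
    t = np.arange(n_frames) / rate
    angles = _smooth_jitter(rng, n_frames, len(DOF_NAMES), rate, jitter_deg)

    segments = []
    for ci, cls in enumerate(classes):
        i0, i1 = ci * seg_frames, (ci + 1) * seg_frames
        tt = np.arange(seg_frames) / rate
        f = base_cadence * cls["speed"]
        slope = cls["slope"]
        h_amp = hip_amp + 0.8 * slope
        k_amp = max(knee_amp - 1.2 * slope, 5.0) if knee_amp > 0 else 0.0
        hip_off = 8.0 + 0.6 * slope
        abd = _WIDTH_ABDUCTION[cls["width"]]
        phase = rng.uniform(0, 2 * np.pi)
        offset = rng.normal(0.0, session_offset_sd, size=len(DOF_NAMES))

        wl = 2 * np.pi * f * tt + phase
        wr = wl + np.pi  # contralateral leg half a cycle later
        block = np.zeros((seg_frames, len(DOF_NAMES)))

        def put(name, traj):
            block[:, DOF_NAMES.index(name)] += traj

        put("LT_X", hip_off + h_amp * np.sin(wl))
        put("RT_X", hip_off + h_amp * np.sin(wr))
        put("LK_X", k_amp * 0.5 * (1 - np.cos(wl + np.pi / 3)))
        put("RK_X", k_amp * 0.5 * (1 - np.cos(wr + np.pi / 3)))
        put("LT_Z", abd * np.sin(wl + np.pi / 2))
        put("RT_Z", -abd * np.sin(wr + np.pi / 2))
        if cls["width"] == "sway":
            put("LB_Z", 8.0 * np.sin(wl))
        # gentle antiphase arm swing
        put("LS_Y", 10.0 * np.sin(wr))
        put("RS_Y", 10.0 * np.sin(wl))
        angles[i0:i1] += amplitude_scale * block + offset[None, :]
        segments.append(
            Segment(i0 / rate, i1 / rate, cls["label"],
                    {k: v for k, v in cls.items() if k != "label"})
        )

    angles = _clip_to_ranges(angles, ranges)
    stream = AngleStream(times=t, angles=angles)
    proto = MotionProtocol(segments=segments, class_set=[s.label for s in segments])
    return stream, proto


# ---------------------------------------------------------------------------
# synchronization squats


def add_sync_squats(
    stream: AngleStream,
    protocol: MotionProtocol | None = None,
    n: int = 5,
    squat_period: float = 2.0,
    depth: float = 100.0,
    rest_s: float = 1.0,
) -> tuple[AngleStream, MotionProtocol | None]:
    """Prepend and append `n` deep squats (knee/hip flexion bursts).

    The squat trains bracket the recording so two independently clocked
    streams can later be synchronized on their peaks.  Protocol segment times
    shift by the length of the leading train.
    """
    if len(stream.times) == 0:
        raise ContractError("stream must be nonempty")
    if n == 0:
        return stream, protocol
    rate = stream.rate
    lead_s = n * squat_period + rest_s
    lead_frames = int(round(lead_s * rate))
    tt = np.arange(lead_frames) / rate
    burst = np.zeros((lead_frames, stream.angles.shape[1]))
    active = tt < n * squat_period
    wave = 0.5 * (1 - np.cos(2 * np.pi * tt[active] / squat_period))
    for name, scale in (("LK_X", 1.0), ("RK_X", 1.0), ("LT_X", 0.6), ("RT_X", 0.6)):
        burst[active, DOF_NAMES.index(name)] = depth * scale * wave

    angles = np.vstack([burst, stream.angles, burst])
    times = np.arange(len(angles)) / rate
    out_stream = AngleStream(times=times, angles=angles, dof_names=stream.dof_names)
    out_proto = protocol.shifted(lead_s) if protocol is not None else None
    return out_stream, out_proto
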