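"""Forward model from posed geometry to 40 Hz capacitance streams.

A capacitive textile strain sensor behaves, to first order, like a parallel
plate capacitor whose dielectric thins as the strip stretches: capacitance
rises monotonically with strain.  The simulator uses a linear gauge law

    C(s, t) = c_base * (1 + g * max(s, 0)) + c_trace + drift(channel, t) + eps

with strain s measured as the relative change of the sensor's surface-path
length, a constant parasitic offset from the conductive interconnect traces,
an additive sweat-drift field that starts at seed regions (default armpits
and knees) and propagates over the skin at a finite speed, and Gaussian
channel noise from a per-channel seeded generator.  Fabric buckles rather
than compresses, so compressive strain clamps at a configurable floor and
contributes no signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body import Skeleton, SkinnedMesh, forward_kinematics, skin_points, skinning_matrices, rotation_from_euler_deg
from .errors import ConfigurationError, ContractError
from .motion import AngleStream
from .placement import GeodesicSolver, SensorSpec, SuitDesign

SENSOR_RATE = 40.0  # Hz of the acquisition unit
STRAIN_FLOOR = -0.05


@dataclass
class SensorParams:
    """Electrical parameters of one sensor family.

    c_base   -- capacitance at zero strain, pF
    gauge    -- dimensionless gain g in C = c_base * (1 + g s)
    c_trace  -- parasitic trace capacitance, pF
    noise_sd -- Gaussian read noise, pF
    seed     -- master seed; per-channel substreams are spawned from it
    """

    c_base: float = 100.0
    gauge: float = 1.0
    c_trace: float = 5.0
    noise_sd: float = 0.05
    seed: int = 0
    strain_floor: float = STRAIN_FLOOR

    def __post_init__(self):
        if self.c_base <= 0 or self.gauge <= 0 or self.noise_sd < 0:
            raise ConfigurationError("require c_base > 0, gauge > 0, noise_sd >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SensorParams":
        with open(path) as fh:
            return cls(**json.load(fh))


#: named body locations usable as drift seed regions -> (joint, offset in m)
_REGION_ANCHORS = {
    "left_armpit": ("LS", np.array([-0.04, -0.06, 0.0])),
    "right_armpit": ("RS", np.array([0.04, -0.06, 0.0])),
    "left_knee": ("LK", np.array([0.0, 0.0, 0.0])),
    "right_knee": ("RK", np.array([0.0, 0.0, 0.0])),
    "chest": ("T", np.array([0.0, -0.05, 0.08])),
    "pelvis": ("LB", np.array([0.0, 0.0, 0.0])),
}


@dataclass
class DriftModel:
    """Sweat-drift field: starts at seed regions and spreads over the skin.

    A channel's drift onset is delayed by its geodesic distance from the
    nearest seed region divided by ``propagation_speed`` (plus the global
    ``onset_time``); after onset the drift rises along a saturating
    exponential to ``max_drift``.
    """

    seed_regions: tuple[str, ...] = ("left_armpit", "right_armpit", "left_knee", "right_knee")
    onset_time: float = 120.0
    propagation_speed: float = 0.003  # m/s over the skin
    max_drift: float = 10.0  # pF
    tau: float = 300.0  # s, saturation time constant

    def __post_init__(self):
        if self.propagation_speed <= 0 or self.tau <= 0 or self.max_drift < 0:
            raise ConfigurationError("drift parameters must be positive (max_drift >= 0)")


@dataclass
class DriftField:
    """Resolved per-channel drift functions: onset delays + saturating rise."""

    onsets: np.ndarray  # (channels,) s
    max_drift: float
    tau: float

    def __call__(self, t, channel: int | None = None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        onsets = self.onsets if channel is None else self.onsets[channel]
        if channel is None:
            dt = np.clip(t[..., None] - onsets[None, :], 0.0, None)
        else:
            dt = np.clip(t - onsets, 0.0, None)
        return self.max_drift * (1.0 - np.exp(-dt / self.tau))


def region_point(skeleton: Skeleton, name: str) -> np.ndarray:
    """Rest-space 3D anchor of a named drift seed region."""
    if name not in _REGION_ANCHORS:
        raise ConfigurationError(
            f"unknown region {name!r}; known: {sorted(_REGION_ANCHORS)}"
        )
    joint, offset = _REGION_ANCHORS[name]
    pos = skeleton.rest_world_positions()[skeleton.joint_index(joint)]
    # mirror the lateral offset for right-side joints
    off = offset.copy()
    if joint.startswith("R"):
        off[0] = -off[0]
    return pos + off


def build_drift_field(
    design: SuitDesign,
    skeleton: Skeleton,
    mesh: SkinnedMesh,
    model: DriftModel,
    solver: GeodesicSolver | None = None,
) -> DriftField:
    """Per-channel onset delays from the geodesic distance to the seed regions."""
    if solver is None:
        solver = GeodesicSolver(mesh.vertices, mesh.faces)
    seeds = [region_point(skeleton, r) for r in model.seed_regions]
    seed_vertices = np.array(
        [int(np.argmin(np.linalg.norm(mesh.vertices - p, axis=1))) for p in seeds]
    )
    dist = solver.distances_from(seed_vertices)[: len(mesh.vertices)]
    onsets = np.empty(len(design.sensors))
    for i, s in enumerate(design.sensors):
        mid = s.path_points[len(s.path_points) // 2]
        v = int(np.argmin(np.linalg.norm(mesh.vertices - mid, axis=1)))
        onsets[i] = model.onset_time + dist[v] / model.propagation_speed
    return DriftField(onsets=onsets, max_drift=model.max_drift, tau=model.tau)


def channel_rng(seed: int, channel: int) -> np.random.Generator:
    """Independent, reproducible per-channel noise stream."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(channel,)))


def capacitance_response(
    s: float | np.ndarray,
    t: float | np.ndarray,
    params: SensorParams,
    drift: DriftField | None = None,
    channel: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Capacitance (pF) for strain `s` at time `t` on one channel.

    Strictly increasing in s >= 0 at fixed t in the zero-noise limit.  Noise
    is drawn from the per-channel seeded generator (pass ``rng`` to continue
    an existing stream).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < params.strain_floor - 1e-12):
        raise ContractError(f"strain below the clamp floor {params.strain_floor}")
    c = params.c_base * (1.0 + params.gauge * np.clip(s, 0.0, None)) + params.c_trace
    if drift is not None:
        c = c + drift(np.asarray(t, dtype=float), channel=channel)
    if params.noise_sd > 0:
        if rng is None:
            rng = channel_rng(params.seed, channel)
        c = c + rng.normal(0.0, params.noise_sd, size=np.shape(c))
    return c


@dataclass
class SensorStream:
    """Simulated (or recorded) capacitance stream at a nominal 40 Hz, pF."""

    times: np.ndarray
    values: np.ndarray  # (frames, channels)
    channel_names: list[str] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or len(self.values) != len(self.times):
            raise ContractError("values must be (frames, channels)")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ContractError("times must be strictly increasing")
        if self.channel_names is None:
            self.channel_names = [f"ch{c:02d}" for c in range(self.values.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times))) if len(self.times) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorStream":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ContractError("sensor CSV must contain a time_s column")
        names = [c for c in df.columns if c != "time_s"]
        return cls(times=df["time_s"].to_numpy(), values=df[names].to_numpy(), channel_names=names)


# ---------------------------------------------------------------------------
# strain & stream simulation


def sensor_strain(
    spec: SensorSpec,
    skeleton: Skeleton,
    pose,
    floor: float = STRAIN_FLOOR,
) -> float:
    """Strain of one sensor at one pose: (L_posed - L_rest) / L_rest.

    The strip's path is fixed in material coordinates; its posed length is the
    skinned polyline length.  Negative (slack) strain clamps at `floor`
    because fabric buckles rather than compresses.
    """
    if spec.rest_length <= 1e-9:
        raise ContractError("degenerate sensor rest length")
    mats = skinning_matrices(skeleton, forward_kinematics(skeleton, pose))
    posed = skin_points(spec.path_points, spec.path_weights, mats)
    length = float(np.linalg.norm(np.diff(posed, axis=0), axis=1).sum())
    s = (length - spec.rest_length) / spec.rest_length
    return float(max(s, floor))


def batch_fk_matrices(skeleton: Skeleton, angle_table: np.ndarray) -> np.ndarray:
    """Skinning matrices for many poses at once: (F, J, 4, 4).

    Vectorised over frames; loops only over the 13 joints.
    """
    F = len(angle_table)
    J = skeleton.n_joints
    rots = rotation_from_euler_deg(angle_table.reshape(F, J, 3).reshape(-1, 3)).reshape(F, J, 3, 3)
    pre_R = np.empty((F, J, 3, 3))
    pre_t = np.empty((F, J, 3))
    world_R = np.empty((F, J, 3, 3))
    world_t = np.empty((F, J, 3))
    eye = np.broadcast_to(np.eye(3), (F, 3, 3))
    for j in range(J):
        p = skeleton.parent[j]
        if p < 0:
            base_R, base_t = eye, np.zeros((F, 3))
        elif skeleton.attach_pre[j]:
            base_R, base_t = pre_R[:, p], pre_t[:, p]
        else:
            base_R, base_t = world_R[:, p], world_t[:, p]
        pre_R[:, j] = base_R
        pre_t[:, j] = base_t + np.einsum("fab,b->fa", base_R, skeleton.rest_offset[j])
        world_R[:, j] = base_R @ rots[:, j]
        world_t[:, j] = pre_t[:, j]
    rest = skeleton.rest_world_positions()
    mats = np.zeros((F, J, 4, 4))
    mats[:, :, :3, :3] = world_R
    mats[:, :, :3, 3] = world_t - np.einsum("fjab,jb->fja", world_R, rest)
    mats[:, :, 3, 3] = 1.0
    return mats


def path_lengths_over_frames(
    design: SuitDesign,
    skeleton: Skeleton,
    angle_table: np.ndarray,
    chunk: int = 2000,
) -> np.ndarray:
    """(frames, channels) posed path lengths of every sensor strip."""
    pts = np.vstack([s.path_points for s in design.sensors])
    wts = np.vstack([s.path_weights for s in design.sensors])
    counts = np.array([len(s.path_points) for s in design.sensors])
    stops = np.cumsum(counts)
    starts = stops - counts
    # consecutive-diff mask: drop the joins between different sensors
    keep = np.ones(len(pts) - 1, dtype=bool)
    keep[stops[:-1] - 1] = False
    seg_owner = np.repeat(np.arange(len(counts)), counts - 1)

    F = len(angle_table)
    out = np.empty((F, len(counts)))
    for i0 in range(0, F, chunk):
        i1 = min(i0 + chunk, F)
        mats = batch_fk_matrices(skeleton, angle_table[i0:i1])
        posed = skin_points(pts, wts, mats)  # (f, P, 3)
        seg = np.linalg.norm(np.diff(posed, axis=1), axis=2)[:, keep]  # (f, S)
        for c in range(len(counts)):
            out[i0:i1, c] = seg[:, seg_owner == c].sum(axis=1)
    return out


def simulate_stream(
    skeleton: Skeleton,
    design: SuitDesign,
    angles: AngleStream,
    params: SensorParams | None = None,
    drift: DriftField | None = None,
    rate: float = SENSOR_RATE,
) -> SensorStream:
    """Simulate the multichannel capacitance stream for a motion.

    The angle stream is linearly interpolated to the sensor timestamps
    (default 40 Hz); each channel's strain follows its strip's posed path
    length; capacitance adds gauge response, trace parasitics, drift and
    seeded per-channel noise.  Reproducible for a fixed seed.
    """
    if design.n_channels == 0 or len(angles.times) < 2:
        raise ContractError("need a nonempty design and an angle stream with >= 2 frames")
    params = params or SensorParams()

    t = np.arange(angles.times[0], angles.times[-1] + 1e-9, 1.0 / rate)
    table = np.empty((len(t), angles.angles.shape[1]))
    for d in range(angles.angles.shape[1]):
        table[:, d] = np.interp(t, angles.times, angles.angles[:, d])

    lengths = path_lengths_over_frames(design, skeleton, table)
    rest = np.array([s.rest_length for s in design.sensors])
    strain = np.clip((lengths - rest[None, :]) / rest[None, :], params.strain_floor, None)

    values = params.c_base * (1.0 + params.gauge * np.clip(strain, 0.0, None)) + params.c_trace
    if drift is not None:
        values = values + drift(t)
    if params.noise_sd > 0:
        for c in range(design.n_channels):
            values[:, c] += channel_rng(params.seed, c).normal(0.0, params.noise_sd, size=len(t))
    return SensorStream(times=t, values=values)
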