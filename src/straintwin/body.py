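"""Procedural articulated body with a skinned triangle mesh.

The body is a kinematic tree of 13 joints (39 rotational degrees of freedom,
three Euler axes per joint) wrapped in a single watertight skin.  The skin is
built as the smooth-min union of one capsule per bone, extracted with marching
cubes, and deformed by linear blend skinning (LBS) with distance-based weights
that blend smoothly across joints.  Conventions: right-handed, Y-up, meters;
joint rotations are intrinsic X->Y->Z Euler angles in degrees everywhere at
the public surface.

The 11 joints tracked by optical motion capture in the reference protocols
(LE, LS, RE, RS, UB, LB, T, LT, RT, LK, RK) are present, plus the two collar
joints (LC, RC) to complete the 13-joint / 39-DoF bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation
from skimage import measure

from .errors import ConfigurationError, ContractError

AXES = ("X", "Y", "Z")

#: Joint names in kinematic (topological) order; LB (lower back / pelvis) is root.
JOINT_ORDER = (
    "LB", "UB", "T", "LC", "LS", "LE", "RC", "RS", "RE", "LT", "LK", "RT", "RK",
)

#: The single-joint sweep protocol's joint order (upper body first, then lower).
PROTOCOL_JOINT_ORDER = ("LE", "LS", "RE", "RS", "UB", "LB", "T", "LT", "RT", "LK", "RK")

_PARENT = {
    "LB": None, "UB": "LB", "T": "UB",
    "LC": "T", "LS": "LC", "LE": "LS",
    "RC": "T", "RS": "RC", "RE": "RS",
    "LT": "LB", "LK": "LT", "RT": "LB", "RK": "RT",
}


@dataclass(frozen=True)
class Skeleton:
    """Articulated joint hierarchy.

    joints      -- joint names, topologically ordered (parents first)
    parent      -- per-joint parent index (-1 for the root)
    rest_offset -- per-joint translation from the parent joint, meters,
                   expressed in the parent's rest frame
    dof_axes    -- per-joint ordered rotation axes
    """

    joints: tuple[str, ...]
    parent: np.ndarray
    rest_offset: np.ndarray
    dof_axes: tuple[tuple[str, ...], ...]
    #: joints attached to the parent's pre-rotation frame (the hips hang from
    #: the pelvis and must not follow lumbar flexion of the LB joint)
    attach_pre: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.attach_pre is None:
            object.__setattr__(self, "attach_pre", np.zeros(len(self.joints), dtype=bool))

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def n_dof(self) -> int:
        return int(sum(len(a) for a in self.dof_axes))

    @property
    def dof_names(self) -> list[str]:
        """Flat DoF names, e.g. 'LE_X', ordered (joint, axis)."""
        return [f"{j}_{ax}" for j, axes in zip(self.joints, self.dof_axes) for ax in axes]

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise ContractError(f"unknown joint {name!r}") from None

    def dof_index(self, joint: str, axis: str) -> int:
        return self.dof_names.index(f"{joint}_{axis}")

    def rest_world_positions(self) -> np.ndarray:
        """(J, 3) joint positions in the rest (identity) pose."""
        pos = np.zeros((self.n_joints, 3))
        for j in range(self.n_joints):
            p = self.parent[j]
            pos[j] = self.rest_offset[j] if p < 0 else pos[p] + self.rest_offset[j]
        return pos


@dataclass
class Pose:
    """Per-DoF joint rotations in degrees, ordered (joint, axis)."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ContractError("pose angles must be a flat vector")
        if not np.all(np.isfinite(self.angles)):
            raise ContractError("pose angles must be finite")

    @classmethod
    def identity(cls, skeleton: Skeleton) -> "Pose":
        return cls(np.zeros(skeleton.n_dof))

    @classmethod
    def from_dict(cls, skeleton: Skeleton, values: dict[str, float]) -> "Pose":
        angles = np.zeros(skeleton.n_dof)
        names = skeleton.dof_names
        for key, val in values.items():
            angles[names.index(key)] = val
        return cls(angles)

    def to_dict(self, skeleton: Skeleton) -> dict[str, float]:
        return dict(zip(skeleton.dof_names, self.angles.tolist()))


@dataclass
class SkinnedMesh:
    """Triangle skin with per-vertex skinning weights.

    vertices -- (N, 3) rest positions, meters
    faces    -- (M, 3) vertex indices
    weights  -- (N, J) LBS weights, rows sum to 1
    """

    vertices: np.ndarray
    faces: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        rowsum = self.weights.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ContractError("skinning weight rows must sum to 1")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self, vertices: np.ndarray | None = None) -> trimesh.Trimesh:
        v = self.vertices if vertices is None else vertices
        return trimesh.Trimesh(vertices=v, faces=self.faces, process=False)

    def export_obj(self, path) -> None:
        self.as_trimesh().export(str(path), file_type="obj")


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the mesh surface: face index plus barycentric coordinates."""

    face: int
    bary: tuple[float, float, float]

    def __post_init__(self):
        b = np.asarray(self.bary, dtype=float)
        if b.shape != (3,) or np.any(b < -1e-12) or abs(b.sum() - 1.0) > 1e-9:
            raise ContractError("barycentric coordinates must be >= 0 and sum to 1")


@dataclass
class BodyConfig:
    """Proportions and meshing parameters of the procedural body (meters).

    ``pitch`` is the marching-cubes voxel size; halving it roughly quadruples
    the face count without moving the skeleton.  ``blend`` is the smooth-min
    radius that rounds the capsule union at joints; ``skin_blend_radius``
    controls how far skinning weights bleed across neighbouring bones.
    """

    spine_lower: float = 0.18   # LB -> UB
    spine_upper: float = 0.22   # UB -> T
    neck_head: float = 0.28     # T -> head top
    collar: float = 0.14        # LC -> LS (shoulder girdle)
    collar_offset: float = 0.06 # T -> LC lateral offset
    upper_arm: float = 0.30
    forearm: float = 0.26
    hip_offset: float = 0.10    # LB -> LT lateral
    hip_drop: float = 0.05      # LB -> LT downward
    thigh: float = 0.42
    shank: float = 0.43
    pelvis_height: float = 1.00
    r_torso_lower: float = 0.11
    r_torso_upper: float = 0.10
    r_neck: float = 0.06
    r_shoulder: float = 0.055
    r_upper_arm: float = 0.045
    r_forearm: float = 0.038
    r_pelvis: float = 0.09
    r_thigh: float = 0.065
    r_shank: float = 0.048
    pitch: float = 0.030
    blend: float = 0.03
    skin_blend_radius: float = 0.05
    weight_prune: float = 0.01

    @classmethod
    def from_json(cls, path) -> "BodyConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def validate(self) -> None:
        for name, val in self.__dict__.items():
            if name == "weight_prune":
                continue
            if not (isinstance(val, (int, float)) and val > 0):
                raise ConfigurationError(f"body config field {name!r} must be positive, got {val!r}")


def _build_skeleton(cfg: BodyConfig) -> Skeleton:
    off = {
        "LB": (0.0, cfg.pelvis_height, 0.0),
        "UB": (0.0, cfg.spine_lower, 0.0),
        "T": (0.0, cfg.spine_upper, 0.0),
        "LC": (cfg.collar_offset, 0.02, 0.0),
        "LS": (cfg.collar, 0.0, 0.0),
        "LE": (cfg.upper_arm, 0.0, 0.0),
        "RC": (-cfg.collar_offset, 0.02, 0.0),
        "RS": (-cfg.collar, 0.0, 0.0),
        "RE": (-cfg.upper_arm, 0.0, 0.0),
        "LT": (cfg.hip_offset, -cfg.hip_drop, 0.0),
        "LK": (0.0, -cfg.thigh, 0.0),
        "RT": (-cfg.hip_offset, -cfg.hip_drop, 0.0),
        "RK": (0.0, -cfg.thigh, 0.0),
    }
    parent = np.array(
        [-1 if _PARENT[j] is None else JOINT_ORDER.index(_PARENT[j]) for j in JOINT_ORDER],
        dtype=np.int64,
    )
    rest = np.array([off[j] for j in JOINT_ORDER])
    attach_pre = np.array([j in ("LT", "RT") for j in JOINT_ORDER])
    return Skeleton(
        joints=JOINT_ORDER,
        parent=parent,
        rest_offset=rest,
        dof_axes=tuple(AXES for _ in JOINT_ORDER),
        attach_pre=attach_pre,
    )


def _bones(skeleton: Skeleton, cfg: BodyConfig) -> list[tuple[int, np.ndarray, np.ndarray, float]]:
    """(owner joint index, start, end, radius) per capsule, rest pose."""
    p = {name: pos for name, pos in zip(skeleton.joints, skeleton.rest_world_positions())}
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    segs = [
        ("LB", p["LB"], p["UB"], cfg.r_torso_lower),
        ("UB", p["UB"], p["T"], cfg.r_torso_upper),
        ("T", p["T"], p["T"] + cfg.neck_head * y, cfg.r_neck),
        ("LC", p["LC"], p["LS"], cfg.r_shoulder),
        ("LS", p["LS"], p["LE"], cfg.r_upper_arm),
        ("LE", p["LE"], p["LE"] + cfg.forearm * x, cfg.r_forearm),
        ("RC", p["RC"], p["RS"], cfg.r_shoulder),
        ("RS", p["RS"], p["RE"], cfg.r_upper_arm),
        ("RE", p["RE"], p["RE"] - cfg.forearm * x, cfg.r_forearm),
        ("LB", p["LB"], p["LT"], cfg.r_pelvis),
        ("LT", p["LT"], p["LK"], cfg.r_thigh),
        ("LK", p["LK"], p["LK"] - cfg.shank * y, cfg.r_shank),
        ("LB", p["LB"], p["RT"], cfg.r_pelvis),
        ("RT", p["RT"], p["RK"], cfg.r_thigh),
        ("RK", p["RK"], p["RK"] - cfg.shank * y, cfg.r_shank),
    ]
    return [(skeleton.joint_index(j), a, b, r) for j, a, b, r in segs]


def _capsule_sdf(points: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = a + np.outer(np.atleast_1d(t), ab) if denom > 0 else np.broadcast_to(a, points.shape)
    return np.linalg.norm(points - closest, axis=-1) - r


def _smooth_min(d1: np.ndarray, d2: np.ndarray, k: float) -> np.ndarray:
    h = np.clip(0.5 + 0.5 * (d2 - d1) / k, 0.0, 1.0)
    return d2 * (1 - h) + d1 * h - k * h * (1 - h)


def build_body_from_bones(
    skeleton: Skeleton,
    bones: list[tuple[int, np.ndarray, np.ndarray, float]],
    pitch: float = 0.03,
    blend: float = 0.03,
    skin_blend_radius: float = 0.05,
    weight_prune: float = 0.01,
) -> SkinnedMesh:
    """Smooth-min union of capsules -> marching cubes -> skinning weights.

    `bones` is a list of (owner joint index, start, end, radius) in rest-space
    world coordinates.  Deterministic for fixed inputs.
    """
    ends = np.array([pt for _, a, b, _ in bones for pt in (a, b)])
    rmax = max(r for *_, r in bones)
    lo = ends.min(axis=0) - rmax - 3 * pitch
    hi = ends.max(axis=0) + rmax + 3 * pitch
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    grid = np.stack(
        np.meshgrid(*(lo[i] + pitch * np.arange(shape[i]) for i in range(3)), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)

    sdf = None
    for _, a, b, r in bones:
        d = _capsule_sdf(grid, a, b, r)
        sdf = d if sdf is None else _smooth_min(sdf, d, blend)
    vol = sdf.reshape(tuple(shape))

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # keep the largest connected component (tiny slivers can appear at grid edges)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda m: len(m.vertices))
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)

    weights = _skinning_weights(verts, skeleton, bones, skin_blend_radius, weight_prune)
    return SkinnedMesh(vertices=verts, faces=faces, weights=weights)


def build_capsule_body(config: BodyConfig | dict | None = None) -> tuple[Skeleton, SkinnedMesh]:
    """Build the 13-joint skeleton and its smoothly blended capsule skin.

    Deterministic for a fixed config.  Raises ConfigurationError on
    non-positive dimensions.
    """
    if config is None:
        config = BodyConfig()
    elif isinstance(config, dict):
        config = BodyConfig(**config)
    config.validate()

    skeleton = _build_skeleton(config)
    bones = _bones(skeleton, config)
    mesh = build_body_from_bones(
        skeleton, bones,
        pitch=config.pitch, blend=config.blend,
        skin_blend_radius=config.skin_blend_radius,
        weight_prune=config.weight_prune,
    )
    return skeleton, mesh


def build_two_bone_body(
    length: float = 0.30,
    radius: float = 0.05,
    pitch: float = 0.015,
    blend: float = 0.02,
    skin_blend_radius: float = 0.03,
) -> tuple[Skeleton, SkinnedMesh]:
    """Minimal single-hinge test body: two capsules stacked along +Y.

    The 'hinge' joint sits between the segments; bending it about X folds the
    upper capsule over the lower one.  Useful as a brute-force-checkable
    fixture for placement and sensing.
    """
    skeleton = Skeleton(
        joints=("base", "hinge"),
        parent=np.array([-1, 0], dtype=np.int64),
        rest_offset=np.array([[0.0, 0.0, 0.0], [0.0, length, 0.0]]),
        dof_axes=(AXES, AXES),
    )
    origin = np.zeros(3)
    mid = np.array([0.0, length, 0.0])
    top = np.array([0.0, 2 * length, 0.0])
    bones = [(0, origin, mid, radius), (1, mid, top, radius)]
    mesh = build_body_from_bones(
        skeleton, bones, pitch=pitch, blend=blend, skin_blend_radius=skin_blend_radius
    )
    return skeleton, mesh


def _skinning_weights(verts, skeleton, bones, sigma: float, prune: float) -> np.ndarray:
    """Distance-based weights with Gaussian falloff over the blend radius.

    A bone's 'distance' to a vertex is its surface distance plus the axial
    overshoot past the segment's ends.  The overshoot term grows linearly with
    distance beyond the joint (pure radial distance grows only quadratically
    there), which keeps the weight transition localized to roughly +-sigma
    around each joint plane instead of smearing across half a limb.
    """
    J = skeleton.n_joints
    dist = np.full((len(verts), J), np.inf)
    for j, a, b, r in bones:
        ab = b - a
        length = float(np.linalg.norm(ab))
        u = ab / length
        t = (verts - a) @ u
        overshoot = np.maximum(np.maximum(-t, t - length), 0.0)
        surface = np.maximum(_capsule_sdf(verts, a, b, r), 0.0)
        dist[:, j] = np.minimum(dist[:, j], surface + overshoot)
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    w[~np.isfinite(w)] = 0.0
    zero = w.sum(axis=1) <= 0
    if zero.any():  # distant slivers: fall back to the nearest bone
        w[zero, np.argmin(dist[zero], axis=1)] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    if prune > 0:
        w[w < prune] = 0.0
        w /= w.sum(axis=1, keepdims=True)
    return w


def rotation_from_euler_deg(angles_xyz: np.ndarray) -> np.ndarray:
    """Intrinsic X->Y->Z rotation matrix/matrices from degrees.

    Accepts (..., 3) and returns (..., 3, 3).
    """
    return Rotation.from_euler("XYZ", np.asarray(angles_xyz, float), degrees=True).as_matrix()


def forward_kinematics(
    skeleton: Skeleton,
    pose: Pose | np.ndarray,
    root_transform: np.ndarray | None = None,
) -> np.ndarray:
    """World-frame 4x4 rigid transforms per joint.

    Child world transform = parent world transform o translate(rest offset)
    o local Euler rotation.  Joints flagged ``attach_pre`` hang from the
    parent's pre-rotation frame (the hips from the pelvis).  An optional
    ``root_transform`` rigidly moves the whole body.
    """
    angles = pose.angles if isinstance(pose, Pose) else np.asarray(pose, float)
    if angles.shape != (skeleton.n_dof,):
        raise ContractError(
            f"pose has {angles.shape} angles; skeleton expects ({skeleton.n_dof},)"
        )
    J = skeleton.n_joints
    rots = rotation_from_euler_deg(angles.reshape(J, 3))
    root = np.eye(4) if root_transform is None else np.asarray(root_transform, float)
    pre = np.zeros((J, 4, 4))
    post = np.zeros((J, 4, 4))
    for j in range(J):
        p = skeleton.parent[j]
        base = root if p < 0 else (pre[p] if skeleton.attach_pre[j] else post[p])
        trans = np.eye(4)
        trans[:3, 3] = skeleton.rest_offset[j]
        pre[j] = base @ trans
        rot = np.eye(4)
        rot[:3, :3] = rots[j]
        post[j] = pre[j] @ rot
    return post


def skinning_matrices(skeleton: Skeleton, world: np.ndarray) -> np.ndarray:
    """(J, 4, 4) matrices mapping rest-space points to posed space per joint."""
    rest_pos = skeleton.rest_world_positions()
    out = np.empty_like(world)
    for j in range(len(world)):
        inv_bind = np.eye(4)
        inv_bind[:3, 3] = -rest_pos[j]
        out[j] = world[j] @ inv_bind
    return out


def skin_vertices(mesh: SkinnedMesh, skeleton: Skeleton, world: np.ndarray) -> np.ndarray:
    """Pose the skin by linear blend skinning; identity transforms reproduce rest."""
    if world.shape[0] != skeleton.n_joints:
        raise ContractError("transform count must equal joint count")
    M = skinning_matrices(skeleton, world)
    return skin_points(mesh.vertices, mesh.weights, M)


def skin_points(rest_points: np.ndarray, weights: np.ndarray, skin_mats: np.ndarray) -> np.ndarray:
    """LBS for arbitrary rest-space points with per-point weights.

    rest_points (P,3); weights (P,J); skin_mats (J,4,4) or (F,J,4,4).
    Returns (P,3) or (F,P,3).
    """
    batched = skin_mats.ndim == 4
    mats = skin_mats if batched else skin_mats[None]
    R = mats[..., :3, :3]
    t = mats[..., :3, 3]
    posed = np.einsum("pj,fjab,pb->fpa", weights, R, rest_points, optimize=True)
    posed += np.einsum("pj,fja->fpa", weights, t, optimize=True)
    return posed if batched else posed[0]


def pose_mesh(mesh: SkinnedMesh, skeleton: Skeleton, pose: Pose | np.ndarray) -> np.ndarray:
    """Convenience: FK + LBS in one call, returning posed vertices."""
    return skin_vertices(mesh, skeleton, forward_kinematics(skeleton, pose))


def surface_point_position(mesh: SkinnedMesh, posed_vertices: np.ndarray, p: SurfacePoint) -> np.ndarray:
    """Barycentric interpolation of a surface point on the posed mesh."""
    if not (0 <= p.face < len(mesh.faces)):
        raise ContractError(f"face index {p.face} out of range")
    tri = posed_vertices[mesh.faces[p.face]]
    return np.asarray(p.bary) @ tri


def surface_point_weights(mesh: SkinnedMesh, p: SurfacePoint) -> np.ndarray:
    """(J,) skinning weights of a surface point (barycentric blend of its face)."""
    return np.asarray(p.bary) @ mesh.weights[mesh.faces[p.face]]


def load_obj(path) -> trimesh.Trimesh:
    """Load a user-supplied rest mesh (OBJ)."""
    return trimesh.load(str(path), file_type="obj", process=False)
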