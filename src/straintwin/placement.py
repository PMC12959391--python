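"""Sensor placement by geodesic-stretch grid search.

A textile strain sensor is a thin strip sewn along a line on the skin; it
responds to the change in surface (geodesic) length between its endpoints as
joints move.  This module

* computes geodesic distances on the skin with Dijkstra on the mesh edge
  graph augmented with edge-midpoint subdivision (a simple, oracle-checkable
  approximation of exact polyhedral geodesics whose error shrinks with mesh
  refinement),
* enumerates placement candidates around each joint on a spatial grid of
  center vertices x tangent directions (default every 15 deg, mod 180),
* scores each candidate by the maximum relative change of its surface-path
  length over a sweep of the joint's movement range, and
* greedily selects the highest-scoring, non-overlapping candidates into a
  suit design (default 38 sensors over 13 joints).

The sensor path is fixed in material (rest-mesh) coordinates; its posed
length is the length of the skinned polyline.  This models a strip attached
to the fabric: the strip cannot re-route to a shorter path when the body
moves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

from .body import (
    Pose,
    Skeleton,
    SkinnedMesh,
    SurfacePoint,
    forward_kinematics,
    skin_points,
    skinning_matrices,
)
from .errors import ContractError, NoPathError

DEFAULT_SENSOR_LENGTH = 0.16  # m, the 160 mm strip
DEFAULT_SENSOR_WIDTH = 0.010  # m, used as the overlap threshold
DEFAULT_DIRECTION_STEP = 15.0  # degrees
DEFAULT_GRID_SPACING = 0.03  # m between candidate centers
DEFAULT_JOINT_RADIUS = 0.12  # m geodesic radius of the candidate neighborhood
SWEEP_SAMPLES = 9  # poses per DoF when sweeping a joint range


# ---------------------------------------------------------------------------
# geodesics


class GeodesicSolver:
    """Dijkstra geodesics on a midpoint-subdivided mesh edge graph.

    Nodes are the mesh vertices plus one midpoint per edge; within every face
    the three corners and three midpoints are fully interconnected with
    Euclidean weights.  Sources/targets given as barycentric surface points
    are attached to the six nodes of their face.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, subdivide: bool = True):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.subdivide = subdivide
        nv = len(self.vertices)

        edges = {}
        if subdivide:
            for f in self.faces:
                for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                    key = (min(a, b), max(a, b))
                    if key not in edges:
                        edges[key] = nv + len(edges)
            mids = np.array(
                [0.5 * (self.vertices[a] + self.vertices[b]) for a, b in edges]
            ).reshape(-1, 3)
            self.nodes = np.vstack([self.vertices, mids]) if len(mids) else self.vertices
        else:
            self.nodes = self.vertices
        self._edge_mid = edges

        pair_set = set()
        self._face_nodes = np.empty((len(self.faces), 6 if subdivide else 3), dtype=np.int64)
        for fi, f in enumerate(self.faces):
            ids = list(f)
            if subdivide:
                for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                    ids.append(edges[(min(a, b), max(a, b))])
            self._face_nodes[fi] = ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    u, v = ids[i], ids[j]
                    pair_set.add((u, v) if u < v else (v, u))
        pairs = np.array(sorted(pair_set), dtype=np.int64)  # deduplicated: coo sums duplicates
        rows, cols = pairs[:, 0], pairs[:, 1]
        w = np.linalg.norm(self.nodes[rows] - self.nodes[cols], axis=1)
        n = len(self.nodes)
        g = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                       shape=(n, n))
        self.graph = g.tocsr()
        self.n_components = connected_components(self.graph, directed=False, return_labels=False)

    # -- queries ------------------------------------------------------------

    def point_position(self, p: SurfacePoint) -> np.ndarray:
        return np.asarray(p.bary) @ self.vertices[self.faces[p.face]]

    def _anchor(self, p: SurfacePoint) -> tuple[np.ndarray, np.ndarray]:
        """Node ids of p's face and Euclidean hook-up weights from p."""
        ids = self._face_nodes[p.face]
        pos = self.point_position(p)
        return ids, np.linalg.norm(self.nodes[ids] - pos, axis=1)

    def distance(self, a: SurfacePoint, b: SurfacePoint, return_path: bool = False):
        """Geodesic distance (and optionally the polyline path) between two surface points."""
        for p in (a, b):
            if not (0 <= p.face < len(self.faces)):
                raise ContractError(f"face index {p.face} out of range")
        pa, pb = self.point_position(a), self.point_position(b)
        if a.face == b.face:
            d = float(np.linalg.norm(pa - pb))
            return (d, np.vstack([pa, pb])) if return_path else d

        src_ids, src_w = self._anchor(a)
        dst_ids, dst_w = self._anchor(b)
        dmat, pred = dijkstra(self.graph, indices=src_ids, return_predecessors=True)
        through = src_w[:, None] + dmat[:, dst_ids] + dst_w[None, :]
        k = np.unravel_index(np.argmin(through), through.shape)
        best = float(through[k])
        if not np.isfinite(best):
            raise NoPathError("surface points lie on disconnected mesh components")
        if not return_path:
            return best
        # reconstruct node chain from the winning source row
        chain = [int(dst_ids[k[1]])]
        prow = pred[k[0]]
        while prow[chain[-1]] >= 0:
            chain.append(int(prow[chain[-1]]))
        chain.reverse()
        path = np.vstack([pa, self.nodes[chain], pb])
        return best, path

    def distances_from(self, node_ids: np.ndarray) -> np.ndarray:
        """Multi-source distances from graph nodes to every node."""
        return dijkstra(self.graph, indices=np.atleast_1d(node_ids), min_only=True)

    def vertex_distances(self, vertex_id: int) -> np.ndarray:
        """Distances from one mesh vertex to all mesh vertices."""
        return self.distances_from(np.array([vertex_id]))[: len(self.vertices)]


def geodesic_distance(vertices, faces, a: SurfacePoint, b: SurfacePoint, return_path: bool = False):
    """One-shot geodesic query; build a :class:`GeodesicSolver` for repeated use."""
    return GeodesicSolver(vertices, faces).distance(a, b, return_path=return_path)


# ---------------------------------------------------------------------------
# candidates


@dataclass
class PlacementCandidate:
    """One possible sensor strip: a surface path through `center` along `direction`."""

    center: SurfacePoint
    direction: float  # degrees within the tangent plane
    endpoints: tuple[SurfacePoint, SurfacePoint]
    rest_length: float
    joint: str
    path_points: np.ndarray  # (P, 3) material coordinates along the strip
    path_weights: np.ndarray  # (P, J) skinning weights of the path points
    score: float = 0.0

    def __post_init__(self):
        if self.rest_length <= 0:
            raise ContractError("candidate rest_length must be positive")


@dataclass
class SensorSpec:
    """One placed sensor: channel id, endpoints, rest length and owning joint."""

    channel: int
    endpoints: tuple[SurfacePoint, SurfacePoint]
    rest_length: float
    joint: str
    path_points: np.ndarray = field(default=None, repr=False)
    path_weights: np.ndarray = field(default=None, repr=False)


@dataclass
class SuitDesign:
    """The ranked, overlap-filtered sensor set."""

    sensors: list[SensorSpec]
    provenance: list[dict]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return len(self.sensors)

    def to_json(self, path) -> None:
        payload = []
        for s, prov in zip(self.sensors, self.provenance):
            payload.append(
                {
                    "channel": s.channel,
                    "joint": s.joint,
                    "rest_length": s.rest_length,
                    "endpoints": [
                        {"face": int(e.face), "bary": list(map(float, e.bary))}
                        for e in s.endpoints
                    ],
                    "score": prov.get("score"),
                    "direction_deg": prov.get("direction"),
                }
            )
        with open(path, "w") as fh:
            json.dump({"sensors": payload, "warnings": self.warnings}, fh, indent=2)

    def export_paths_obj(self, path) -> None:
        """Write the sensor path polylines as OBJ line elements for inspection."""
        with open(path, "w") as fh:
            offset = 1
            for s in self.sensors:
                pts = s.path_points
                for p in pts:
                    fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
                fh.write("l " + " ".join(str(offset + i) for i in range(len(pts))) + "\n")
                offset += len(pts)


class SurfaceProjector:
    """Closest-point projection onto a triangle mesh (centroid KDTree + exact
    point-triangle tests over the k nearest faces)."""

    def __init__(self, tm: trimesh.Trimesh, k: int = 16):
        from scipy.spatial import cKDTree

        self.tm = tm
        self.triangles = np.asarray(tm.triangles)
        self.k = min(k, len(self.triangles))
        self.tree = cKDTree(self.triangles.mean(axis=1))

    def project(self, points: np.ndarray):
        """Returns (closest points, face ids, barycentric coordinates)."""
        points = np.atleast_2d(points)
        _, idx = self.tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        Q, K = idx.shape
        tris = self.triangles[idx.ravel()]
        rep = np.repeat(points, K, axis=0)
        closest = trimesh.triangles.closest_point(tris, rep)
        d2 = ((closest - rep) ** 2).sum(axis=1).reshape(Q, K)
        best = d2.argmin(axis=1)
        rows = np.arange(Q)
        face_ids = idx[rows, best]
        cpts = closest.reshape(Q, K, 3)[rows, best]
        bary = trimesh.triangles.points_to_barycentric(self.triangles[face_ids], cpts)
        bary = np.clip(bary, 0.0, None)
        bary /= bary.sum(axis=1, keepdims=True)
        return cpts, face_ids, bary


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the tangent plane."""
    ref = np.eye(3)[np.argmin(np.abs(normal))]
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def trace_paths(
    projector: SurfaceProjector,
    starts: np.ndarray,
    directions: np.ndarray,
    half_length: float,
    step: float = 0.01,
) -> np.ndarray:
    """Trace surface polylines in lockstep from `starts` along `directions`.

    Steps `step` along the current direction and re-projects onto the surface,
    approximating a geodesic walk.  Returns (C, S+1, 3) with S = ceil(L/step).
    """
    n_steps = max(1, int(np.ceil(half_length / step)))
    pos = np.array(starts, dtype=float)
    dirs = np.array(directions, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    out = np.empty((len(pos), n_steps + 1, 3))
    out[:, 0] = pos
    for s in range(n_steps):
        raw = pos + step * dirs
        proj, _, _ = projector.project(raw)
        delta = proj - pos
        norms = np.linalg.norm(delta, axis=1, keepdims=True)
        ok = norms[:, 0] > 1e-9
        dirs[ok] = delta[ok] / norms[ok]
        pos = proj
        out[:, s + 1] = pos
    return out


def _polyline_lengths(paths: np.ndarray) -> np.ndarray:
    """Lengths of (..., P, 3) polylines."""
    return np.linalg.norm(np.diff(paths, axis=-2), axis=-1).sum(axis=-1)


def enumerate_candidates(
    skeleton: Skeleton,
    mesh: SkinnedMesh,
    joint: str,
    solver: GeodesicSolver | None = None,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    direction_step: float = DEFAULT_DIRECTION_STEP,
    sensor_length: float = DEFAULT_SENSOR_LENGTH,
    joint_radius: float = DEFAULT_JOINT_RADIUS,
    trace_step: float = 0.01,
) -> list[PlacementCandidate]:
    """All sensor placements near `joint`: grid of centers x tangent directions.

    Directions sample [0, 180) every `direction_step` degrees (a strip has no
    orientation, so directions are taken mod 180).  Ordering is deterministic:
    centers by geodesic distance from the joint, directions ascending.
    """
    if sensor_length <= 0 or grid_spacing <= 0 or direction_step <= 0:
        raise ContractError("sensor_length, grid_spacing and direction_step must be positive")
    jidx = skeleton.joint_index(joint)
    if solver is None:
        solver = GeodesicSolver(mesh.vertices, mesh.faces)
    tm = mesh.as_trimesh()
    projector = SurfaceProjector(tm)

    joint_pos = skeleton.rest_world_positions()[jidx]
    # seed the geodesic neighborhood from the whole ring of vertices nearest
    # the joint, so the neighborhood wraps the full limb circumference instead
    # of biasing toward one arbitrary closest vertex
    eu = np.linalg.norm(mesh.vertices - joint_pos, axis=1)
    ring = np.nonzero(eu <= eu.min() + 0.3 * max(eu.min(), 0.03))[0]
    vdist = solver.distances_from(ring)[: len(mesh.vertices)]
    near = np.nonzero(vdist < joint_radius)[0]
    if len(near) == 0:
        return []
    order = near[np.lexsort((near, vdist[near]))]

    centers: list[int] = []
    for v in order:
        if all(np.linalg.norm(mesh.vertices[v] - mesh.vertices[c]) >= grid_spacing for c in centers):
            centers.append(int(v))

    normals = np.asarray(tm.vertex_normals)
    angles = np.arange(0.0, 180.0, direction_step)

    all_starts, all_dirs, meta = [], [], []
    for c in centers:
        u, v = _tangent_frame(normals[c])
        for ang in angles:
            rad = np.deg2rad(ang)
            all_starts.append(mesh.vertices[c])
            all_dirs.append(np.cos(rad) * u + np.sin(rad) * v)
            meta.append((c, float(ang)))
    if not all_starts:
        return []
    starts = np.array(all_starts)
    dirs = np.array(all_dirs)

    half = sensor_length / 2.0
    fwd = trace_paths(projector, starts, dirs, half, step=trace_step)
    bwd = trace_paths(projector, starts, -dirs, half, step=trace_step)
    paths = np.concatenate([bwd[:, ::-1], fwd[:, 1:]], axis=1)  # (C, P, 3)

    flat = paths.reshape(-1, 3)
    _, tri_ids, bary = projector.project(flat)
    weights_flat = np.einsum("pk,pkj->pj", bary, mesh.weights[mesh.faces[tri_ids]])
    P = paths.shape[1]
    weights = weights_flat.reshape(len(paths), P, -1)
    tri_ids = tri_ids.reshape(len(paths), P)
    bary = bary.reshape(len(paths), P, 3)

    out = []
    for i, (c, ang) in enumerate(meta):
        rest_len = float(_polyline_lengths(paths[i]))
        if rest_len <= 0:
            continue
        ep = tuple(
            SurfacePoint(face=int(tri_ids[i, k]), bary=tuple(bary[i, k]))
            for k in (0, P - 1)
        )
        center_sp = SurfacePoint(face=int(tri_ids[i, P // 2]), bary=tuple(bary[i, P // 2]))
        out.append(
            PlacementCandidate(
                center=center_sp,
                direction=ang,
                endpoints=ep,
                rest_length=rest_len,
                joint=joint,
                path_points=paths[i],
                path_weights=weights[i],
            )
        )
    return out


# ---------------------------------------------------------------------------
# scoring & selection


def joint_sweep(
    skeleton: Skeleton,
    joint: str,
    ranges: dict[str, tuple[float, float]],
    n: int = SWEEP_SAMPLES,
) -> list[Pose]:
    """Poses sweeping each DoF of `joint` across its range, others at rest."""
    jidx = skeleton.joint_index(joint)
    poses = []
    for k, axis in enumerate(skeleton.dof_axes[jidx]):
        name = f"{joint}_{axis}"
        lo, hi = ranges.get(name, (0.0, 0.0))
        for a in np.linspace(lo, hi, n):
            angles = np.zeros(skeleton.n_dof)
            angles[3 * jidx + k] = a
            poses.append(Pose(angles))
    return poses


def _sweep_matrices(skeleton: Skeleton, sweep: list[Pose]) -> np.ndarray:
    return np.stack(
        [skinning_matrices(skeleton, forward_kinematics(skeleton, p)) for p in sweep]
    )


def stretch_score(
    candidate: PlacementCandidate,
    skeleton: Skeleton,
    sweep: list[Pose],
    mode: str = "absolute",
) -> float:
    """Relative path-length change of the strip over a joint sweep.

    mode='absolute'   -- max |L(pose) - L(rest)| / L(rest)
    mode='elongation' -- max (L(pose) - L(rest)) / L(rest), clipped at 0: the
                         capacitive strip only signals when stretched, so the
                         suit designer ranks candidates by usable elongation
    """
    if not sweep:
        raise ContractError("sweep must contain at least one pose")
    mats = _sweep_matrices(skeleton, sweep)
    posed = skin_points(candidate.path_points, candidate.path_weights, mats)
    lengths = _polyline_lengths(posed)
    delta = lengths - candidate.rest_length
    if mode == "absolute":
        return float(np.max(np.abs(delta)) / candidate.rest_length)
    if mode == "elongation":
        return float(max(np.max(delta), 0.0) / candidate.rest_length)
    raise ContractError(f"unknown score mode {mode!r}")


def score_candidates(
    candidates: list[PlacementCandidate],
    skeleton: Skeleton,
    sweep: list[Pose],
    mode: str = "absolute",
) -> None:
    """Vectorised in-place scoring of many candidates against one sweep."""
    if not candidates:
        return
    mats = _sweep_matrices(skeleton, sweep)
    pts = np.stack([c.path_points for c in candidates])  # (C, P, 3)
    wts = np.stack([c.path_weights for c in candidates])
    C, P, _ = pts.shape
    posed = skin_points(pts.reshape(-1, 3), wts.reshape(C * P, -1), mats)
    posed = posed.reshape(len(mats), C, P, 3)
    lengths = _polyline_lengths(posed)  # (F, C)
    rest = np.array([c.rest_length for c in candidates])
    delta = lengths - rest[None, :]
    if mode == "absolute":
        scores = np.max(np.abs(delta), axis=0) / rest
    elif mode == "elongation":
        scores = np.clip(np.max(delta, axis=0), 0.0, None) / rest
    else:
        raise ContractError(f"unknown score mode {mode!r}")
    for c, s in zip(candidates, scores):
        c.score = float(s)


def default_joint_budget() -> dict[str, int]:
    """Per-joint sensor budget: 3 per joint, 2 for the neck joint T (38 total)."""
    budget = {j: 3 for j in ("LB", "UB", "LC", "LS", "LE", "RC", "RS", "RE", "LT", "LK", "RT", "RK")}
    budget["T"] = 2
    return budget


def design_suit(
    skeleton: Skeleton,
    mesh: SkinnedMesh,
    ranges: dict[str, tuple[float, float]],
    per_joint_budget: dict[str, int] | int | None = None,
    overlap_threshold: float = DEFAULT_SENSOR_WIDTH,
    solver: GeodesicSolver | None = None,
    score_mode: str = "elongation",
    **enumerate_kwargs,
) -> SuitDesign:
    """Greedy descending-score selection of non-overlapping sensors.

    Ranking uses elongation scores by default: a strip that only goes slack
    under the joint's sweep carries no signal (capacitance responds to
    positive strain only), so it must not win a placement.

    A candidate is rejected when any point of its path lies within
    `overlap_threshold` of an accepted sensor's path (paths are densely
    sampled, so point-to-point distance is an accurate proxy for path
    proximity at the 10 mm scale).  Ties break by enumeration order, making
    the design deterministic for fixed inputs.
    """
    if per_joint_budget is None:
        per_joint_budget = default_joint_budget()
    elif isinstance(per_joint_budget, int):
        per_joint_budget = {j: per_joint_budget for j in skeleton.joints}
    if any(b < 1 for b in per_joint_budget.values()):
        raise ContractError("per-joint budgets must be >= 1")

    if solver is None:
        solver = GeodesicSolver(mesh.vertices, mesh.faces)

    accepted: list[PlacementCandidate] = []
    accepted_pts: list[np.ndarray] = []
    provenance: list[dict] = []
    warnings: list[str] = []

    for joint in skeleton.joints:
        if joint not in per_joint_budget:
            continue
        cands = enumerate_candidates(skeleton, mesh, joint, solver=solver, **enumerate_kwargs)
        score_candidates(cands, skeleton, joint_sweep(skeleton, joint, ranges), mode=score_mode)
        order = sorted(range(len(cands)), key=lambda i: (-cands[i].score, i))
        taken = 0
        for i in order:
            if taken >= per_joint_budget[joint]:
                break
            cand = cands[i]
            if accepted_pts:
                dmin = min(cdist(cand.path_points, pts).min() for pts in accepted_pts)
                if dmin < overlap_threshold:
                    continue
            accepted.append(cand)
            accepted_pts.append(cand.path_points)
            provenance.append(
                {"joint": joint, "score": cand.score, "direction": cand.direction,
                 "rank": int(taken)}
            )
            taken += 1
        if taken < per_joint_budget[joint]:
            warnings.append(
                f"joint {joint}: only {taken}/{per_joint_budget[joint]} non-overlapping sensors found"
            )

    sensors = [
        SensorSpec(
            channel=i,
            endpoints=c.endpoints,
            rest_length=c.rest_length,
            joint=c.joint,
            path_points=c.path_points,
            path_weights=c.path_weights,
        )
        for i, c in enumerate(accepted)
    ]
    return SuitDesign(sensors=sensors, provenance=provenance, warnings=warnings)
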