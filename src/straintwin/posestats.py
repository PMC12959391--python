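"""Joint movement-range statistics from a pose corpus.

Each of the 39 degrees of freedom is summarised by a histogram of 2000 bins
spanning [-180, 180] degrees (bin width 0.18 deg) built over a large corpus of
daily poses; the usable movement range of a DoF is the smallest contiguous bin
span holding at least a requested fraction of the corpus mass (coverage 1
reduces to the min/max support).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

N_BINS = 2000
ANGLE_LO = -180.0
ANGLE_HI = 180.0
BIN_EDGES = np.linspace(ANGLE_LO, ANGLE_HI, N_BINS + 1)
BIN_WIDTH = (ANGLE_HI - ANGLE_LO) / N_BINS  # 0.18 deg


@dataclass
class JointRange:
    """Movement range of one DoF, with its occupancy histogram."""

    dof: tuple[str, str]  # (joint, axis)
    lo: float
    hi: float
    histogram: np.ndarray

    def __post_init__(self):
        if self.lo > self.hi:
            raise ContractError("range lo must not exceed hi")

    @property
    def span(self) -> float:
        return self.hi - self.lo

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)


def _smallest_covering_span(counts: np.ndarray, coverage: float) -> tuple[int, int]:
    """Inclusive bin-index span [i, j] of minimal width holding >= coverage mass."""
    total = counts.sum()
    need = coverage * total
    nz = np.nonzero(counts)[0]
    lo_bin, hi_bin = int(nz[0]), int(nz[-1])
    if coverage >= 1.0:
        return lo_bin, hi_bin
    csum = np.concatenate([[0], np.cumsum(counts)])
    best = (lo_bin, hi_bin)
    j = 0
    for i in range(len(counts)):
        if j < i:
            j = i
        while j < len(counts) and csum[j + 1] - csum[i] < need:
            j += 1
        if j >= len(counts):
            break
        if (j - i) < (best[1] - best[0]):
            best = (i, j)
    return best


def joint_movement_ranges(
    poses: np.ndarray | pd.DataFrame,
    dof_names: list[str] | None = None,
    coverage: float = 0.995,
) -> dict[str, JointRange]:
    """Per-DoF movement ranges from a (frames x DoF) pose table in degrees.

    ``coverage`` is the fraction of corpus mass the reported range must
    contain; 1.0 returns the exact support (min/max occupied bins).
    """
    if isinstance(poses, pd.DataFrame):
        dof_names = list(poses.columns)
        poses = poses.to_numpy(dtype=float)
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 2 or len(poses) == 0:
        raise ContractError("pose corpus must be a nonempty (frames x DoF) table")
    if not (0 < coverage <= 1):
        raise ContractError("coverage must lie in (0, 1]")
    if dof_names is None:
        dof_names = [f"dof{i}" for i in range(poses.shape[1])]

    out: dict[str, JointRange] = {}
    for k, name in enumerate(dof_names):
        counts, _ = np.histogram(poses[:, k], bins=BIN_EDGES)
        i, j = _smallest_covering_span(counts, coverage)
        joint, _, axis = name.rpartition("_")
        out[name] = JointRange(
            dof=(joint or name, axis),
            lo=float(BIN_EDGES[i]),
            hi=float(BIN_EDGES[j + 1]),
            histogram=counts,
        )
    return out


def read_pose_table(path) -> pd.DataFrame:
    """Read a CSV pose table (one row per frame, one column per DoF, degrees)."""
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ContractError("pose table is empty")
    return df


def write_ranges_json(ranges: dict[str, JointRange], path) -> None:
    payload = {
        name: {"joint": r.dof[0], "axis": r.dof[1], "lo": r.lo, "hi": r.hi}
        for name, r in ranges.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_ranges_json(path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: (d["lo"], d["hi"]) for name, d in payload.items()}
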