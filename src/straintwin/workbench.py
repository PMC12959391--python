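"""End-to-end experiment orchestration: design -> simulate -> preprocess ->
train -> evaluate, with a single seed governing every stage.

Presets mirror the study's data-collection regimes:

calibration (MLP angle regression, random 3:1:1 frame split)
  single_joint  -- 11-joint sweep protocol (~387 s), overall mean MAE target
  multijoint    -- 4-min fast calisthenics-like routine
  drift         -- repeated routine with pauses under an active drift field

classification (LSTM, per-class sequential 3:1:1 split)
  pick_place    -- 3 heights x 5 speeds reaches (15 classes)
  gait_speeds / gait_widths / gait_slopes / gait_all  -- treadmill gait
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .body import BodyConfig, build_capsule_body
from .calibration import AngleRegressor, RegressorConfig
from .errors import ConfigurationError
from .motion import (
    DEFAULT_JOINT_RANGES,
    MotionProtocol,
    Segment,
    add_sync_squats,
    gait_protocol,
    multijoint_routine,
    pick_place_protocol,
    single_joint_protocol,
)
from .drift_study import drift_experiment
from .patterns import ClassifierConfig, MotionClassifier
from .placement import GeodesicSolver, design_suit
from .preprocess import (
    align_streams_shared_clock,
    attach_labels,
    crop_to_protocol,
    split_dataset,
    synchronize_streams,
)
from .sensors import DriftModel, SensorParams, simulate_stream

def _package_version() -> str:
    from . import __version__

    return __version__


CALIBRATION_PRESETS = ("single_joint", "multijoint", "drift")
CLASSIFICATION_PRESETS = ("pick_place", "gait_speeds", "gait_widths", "gait_slopes", "gait_all")

_GAIT_SUBSETS = {
    "gait_speeds": dict(speeds=(0.6, 0.8, 1.0, 1.2), widths=(), slopes=()),
    "gait_widths": dict(speeds=(), widths=("narrow-", "narrow", "regular", "wide", "sway"), slopes=()),
    "gait_slopes": dict(speeds=(), widths=(), slopes=(-6.0, -3.0, 0.0, 3.0, 6.0, 9.0)),
    "gait_all": {},
}


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    preset: str
    seed: int = 0
    out_dir: str | None = None
    body: dict = field(default_factory=dict)
    ranges: dict | None = None
    design: dict = field(default_factory=dict)
    sensor: dict = field(default_factory=dict)
    drift: dict | None = None
    protocol: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    subtract_baseline: bool = False

    def __post_init__(self):
        known = CALIBRATION_PRESETS + CLASSIFICATION_PRESETS
        if self.preset not in known:
            raise ConfigurationError(f"unknown preset {self.preset!r}; known: {known}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "preset" not in payload:
            raise ConfigurationError("experiment config is missing the key 'preset'")
        return cls(**payload)


_DESIGN_CACHE: dict = {}


def build_body_and_design(config: ExperimentConfig):
    """Body + optimized suit shared by every preset (deterministic per config).

    Cached in-process: the design depends only on the body config, the ranges
    and the design parameters, so repeated experiments reuse it.
    """
    ranges = config.ranges or DEFAULT_JOINT_RANGES
    key = json.dumps([config.body, ranges, config.design], sort_keys=True, default=str)
    if key not in _DESIGN_CACHE:
        skeleton, mesh = build_capsule_body(BodyConfig(**config.body))
        solver = GeodesicSolver(mesh.vertices, mesh.faces)
        design = design_suit(skeleton, mesh, ranges, solver=solver, **config.design)
        _DESIGN_CACHE[key] = (skeleton, mesh, design, solver)
    skeleton, mesh, design, solver = _DESIGN_CACHE[key]
    return skeleton, mesh, design, solver, ranges


def _generate_protocol(config: ExperimentConfig, ranges):
    kw = dict(config.protocol)
    seed = kw.pop("seed", config.seed)
    if config.preset == "single_joint":
        return single_joint_protocol(ranges=ranges, seed=seed, **kw)
    if config.preset == "multijoint":
        stream = multijoint_routine(ranges=ranges, seed=seed, **kw)
        proto = MotionProtocol(
            segments=[Segment(0.0, stream.duration, "routine")], class_set=["routine"]
        )
        return stream, proto
    if config.preset == "pick_place":
        return pick_place_protocol(ranges=ranges, seed=seed, **kw)
    if config.preset in _GAIT_SUBSETS:
        merged = {**_GAIT_SUBSETS[config.preset], **kw}
        return gait_protocol(ranges=ranges, seed=seed, **merged)
    raise ConfigurationError(f"no generator for preset {config.preset!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a preset end to end; returns (and optionally writes) metrics."""
    t_start = time.time()
    skeleton, mesh, design, solver, ranges = build_body_and_design(config)
    params = SensorParams(seed=config.seed, **config.sensor)
    report: dict = {
        "preset": config.preset,
        "seed": config.seed,
        "version": _package_version(),
        "n_sensors": design.n_channels,
    }

    if config.preset in CALIBRATION_PRESETS:
        reg_cfg = RegressorConfig(seed=config.seed, **config.model)
        if config.preset == "drift":
            drift_model = DriftModel(**(config.drift or {}))
            data, drift_report = drift_experiment(
                skeleton, design, mesh, drift_model,
                params=params, seed=config.seed, solver=solver,
                **{k: v for k, v in config.protocol.items()
                   if k in ("repetitions", "pause_s", "routine")},
            )
            report["onset_order"] = drift_report.onset_order.tolist()
        else:
            stream, proto = _generate_protocol(config, ranges)
            stream, proto = add_sync_squats(stream, proto)
            drift_field = None
            if config.drift is not None:
                from .sensors import build_drift_field

                drift_field = build_drift_field(
                    design, skeleton, mesh, DriftModel(**config.drift), solver=solver
                )
            sensor_stream = simulate_stream(skeleton, design, stream, params, drift=drift_field)
            data = synchronize_streams(sensor_stream, stream)
            if proto is not None:
                data = crop_to_protocol(data, proto)
        data = split_dataset(data, mode="random", seed=config.seed)
        results = AngleRegressor(reg_cfg).fit(data, subtract_baseline=config.subtract_baseline)
        calib = results.evaluate(data, tag="test")
        report.update(
            {
                "overall_mae_deg": calib.overall_mae,
                "per_joint_mae_deg": calib.per_joint,
                "n_test_frames": calib.n_frames,
                "best_val_mse": results.best_val_mse,
            }
        )
    else:
        cls_cfg = ClassifierConfig(seed=config.seed, **config.model)
        stream, proto = _generate_protocol(config, ranges)
        sensor_stream = simulate_stream(skeleton, design, stream, params)
        data = align_streams_shared_clock(sensor_stream, stream)
        attach_labels(data, proto)
        data = split_dataset(data, mode="sequential_by_class", seed=config.seed)
        results = MotionClassifier(cls_cfg).fit(data)
        accuracy, confusion = results.evaluate(data, tag="test")
        per_class = results.per_class_accuracy(confusion)
        report.update(
            {
                "accuracy": accuracy,
                "per_class_accuracy": per_class,
                "n_classes": len(results.class_set),
                "n_majority_correct": int(sum(v > 0.5 for v in per_class.values())),
                "n_test_windows": int(confusion.to_numpy().sum()),
            }
        )

    report["wall_time_s"] = round(time.time() - t_start, 2)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "manifest.json")
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        design.to_json(out / "design.json")
    return report


# ---------------------------------------------------------------------------
# acceptance presets (classification regime at matched protocol scale)


def run_acceptance(seed: int = 0, segment_s: float = 180.0,
                   iterations: int | None = None) -> dict:
    """Recompute the headline gait-classification quantities from scratch.

    Each gait class contributes ``segment_s`` seconds of simulated data
    (three 1-min recordings' worth per class by default); splits are
    per-class sequential 3:1:1 and the classifier is the default 3x50 LSTM
    with one look-back step.  Returns {target: {"value": ..., "n": ...}}.
    """
    model = {} if iterations is None else {"iterations": iterations}
    out = {}
    specs = [
        ("t3", "gait_widths"),
        ("t4", "gait_slopes"),
        ("t5", "gait_speeds"),
        ("t6", "gait_all"),
    ]
    for target, preset in specs:
        cfg = ExperimentConfig(
            preset=preset,
            seed=seed,
            protocol={"segment_s": segment_s},
            model=model,
        )
        rep = run_experiment(cfg)
        if target == "t6":
            out[target] = {"value": float(rep["n_majority_correct"]), "n": rep["n_classes"]}
        else:
            out[target] = {"value": 100.0 * rep["accuracy"], "n": rep["n_test_windows"]}
    return out
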