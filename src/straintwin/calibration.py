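"""Sensor-to-angle regression and drift-baseline mitigation.

The calibrator maps the multichannel capacitance readings of one frame to the
39 joint angles with a multilayer perceptron (five hidden layers of 100
rectified linear units), trained with mean-squared-error loss and Adam
(learning rate 1e-3, epsilon 1e-4) on minibatches of 64 for a fixed number of
gradient steps (default 10,000), keeping the snapshot with the best
validation loss.  Channels are standardized with train-split statistics
before entering the network; angles stay in degrees.

Slow sensor drift can be visualised or subtracted via a Savitzky-Golay
baseline (window 18,000 frames, applied twice, polynomial order 3).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.neural_network import MLPRegressor

from .errors import ContractError
from .preprocess import AlignedDataset


@dataclass
class RegressorConfig:
    """Hyperparameters of the angle-regression MLP (defaults match the
    reference training recipe)."""

    hidden_layers: int = 5
    units: int = 100
    activation: str = "relu"
    learning_rate: float = 1e-3
    epsilon: float = 1e-4
    batch: int = 64
    iterations: int = 10_000
    eval_every: int = 250
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_layers", "units", "learning_rate", "epsilon", "batch", "iterations"):
            if getattr(self, name) <= 0:
                raise ContractError(f"config field {name} must be positive")


@dataclass
class CalibReport:
    """Per-DoF accuracy of a fitted calibrator on held-out frames."""

    dof_names: list[str]
    mae_deg: np.ndarray  # (D,)
    p50_deg: np.ndarray
    p90_deg: np.ndarray
    n_frames: int

    @property
    def overall_mae(self) -> float:
        """DoF-weighted mean of the per-DoF mean absolute errors, degrees."""
        return float(self.mae_deg.mean())

    @property
    def per_joint(self) -> dict[str, float]:
        joints: dict[str, list[float]] = {}
        for name, err in zip(self.dof_names, self.mae_deg):
            joints.setdefault(name.rsplit("_", 1)[0], []).append(float(err))
        return {j: float(np.mean(v)) for j, v in joints.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dof": self.dof_names, "mae_deg": self.mae_deg,
             "p50_deg": self.p50_deg, "p90_deg": self.p90_deg}
        )

    def to_json(self, path) -> None:
        payload = {
            "overall_mae_deg": self.overall_mae,
            "per_joint_mae_deg": self.per_joint,
            "per_dof_mae_deg": dict(zip(self.dof_names, self.mae_deg.tolist())),
            "n_frames": self.n_frames,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class AngleRegressionResults:
    """Fit results: the trained network, diagnostics and evaluation helpers."""

    def __init__(self, model, config, channel_mean, channel_std, dof_names,
                 channel_names, val_history):
        self._model = model
        self.config = config
        self.channel_mean = channel_mean
        self.channel_std = channel_std
        self.dof_names = dof_names
        self.channel_names = channel_names
        self.val_history = val_history  # [(step, val_mse)]

    @property
    def best_val_mse(self) -> float:
        return float(min(m for _, m in self.val_history))

    def predict(self, sensors: np.ndarray) -> np.ndarray:
        """Joint angles (degrees) from raw capacitance frames (F, C)."""
        x = (np.asarray(sensors, float) - self.channel_mean) / self.channel_std
        out = self._model.predict(x)
        return out.reshape(len(x), -1)

    def evaluate(self, data: AlignedDataset, tag: str | None = "test") -> CalibReport:
        """Per-DoF mean absolute error on held-out frames (deterministic)."""
        subset = data.subset(tag) if tag is not None and data.split is not None else data
        pred = self.predict(subset.sensors)
        err = np.abs(pred - subset.angles)
        return CalibReport(
            dof_names=list(self.dof_names),
            mae_deg=err.mean(axis=0),
            p50_deg=np.percentile(err, 50, axis=0),
            p90_deg=np.percentile(err, 90, axis=0),
            n_frames=len(err),
        )

    def summary(self) -> str:
        lines = [
            "Angle regression results",
            "========================",
            f"architecture : {self.config.hidden_layers} x {self.config.units} ReLU MLP",
            f"inputs       : {len(self.channel_names)} channels (z-scored on train split)",
            f"outputs      : {len(self.dof_names)} joint angles (deg)",
            f"training     : {self.config.iterations} Adam steps, batch {self.config.batch}, "
            f"lr {self.config.learning_rate:g}, eps {self.config.epsilon:g}",
            f"best val MSE : {self.best_val_mse:.4f} deg^2",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Checkpoint: network weights + config + standardization constants."""
        arrays = {}
        for i, (w, b) in enumerate(zip(self._model.coefs_, self._model.intercepts_)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(
            path,
            channel_mean=self.channel_mean,
            channel_std=self.channel_std,
            config=json.dumps(asdict(self.config)),
            dof_names=json.dumps(list(self.dof_names)),
            channel_names=json.dumps(list(self.channel_names)),
            **arrays,
        )


class AngleRegressor:
    """Model object: configure, then :meth:`fit` on an aligned, split dataset."""

    def __init__(self, config: RegressorConfig | None = None):
        self.config = config or RegressorConfig()

    def fit(
        self,
        data: AlignedDataset,
        subtract_baseline: bool = False,
        baseline_window: int = 18_000,
    ) -> AngleRegressionResults:
        """Train on the 'train' frames, snapshot on best 'val' loss.

        ``subtract_baseline`` removes the per-channel Savitzky-Golay drift
        baseline (recentered at its start) from the sensors before training.
        """
        cfg = self.config
        if data.split is None:
            raise ContractError("dataset must be split before fitting")
        sensors = data.sensors
        if subtract_baseline:
            base = drift_baseline(sensors, window=baseline_window)
            sensors = sensors - (base - base[0:1, :])
        if not (np.all(np.isfinite(sensors)) and np.all(np.isfinite(data.angles))):
            raise ContractError("inputs contain NaN or infinite values")

        tr, va = data.mask("train"), data.mask("val")
        x_tr, y_tr = sensors[tr], data.angles[tr]
        x_va, y_va = sensors[va], data.angles[va]
        mean = x_tr.mean(axis=0)
        std = np.maximum(x_tr.std(axis=0), 1e-8)
        x_tr = (x_tr - mean) / std
        x_va = (x_va - mean) / std

        net = MLPRegressor(
            hidden_layer_sizes=(cfg.units,) * cfg.hidden_layers,
            activation=cfg.activation,
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            epsilon=cfg.epsilon,
            random_state=cfg.seed,
            max_iter=1,
        )
        rng = np.random.default_rng(cfg.seed)
        best = None
        history = []
        import warnings

        with warnings.catch_warnings():
            # sklearn warns on (n, 1) targets; multioutput form is intentional
            warnings.simplefilter("ignore")
            for step in range(1, cfg.iterations + 1):
                idx = rng.integers(0, len(x_tr), size=cfg.batch)
                net.partial_fit(x_tr[idx], y_tr[idx])
                if step % cfg.eval_every == 0 or step == cfg.iterations:
                    pred = net.predict(x_va).reshape(y_va.shape)
                    val_mse = float(np.mean((pred - y_va) ** 2))
                    history.append((step, val_mse))
                    if best is None or val_mse < best[0]:
                        best = (val_mse, copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_))
        net.coefs_, net.intercepts_ = best[1], best[2]

        return AngleRegressionResults(
            model=net,
            config=cfg,
            channel_mean=mean,
            channel_std=std,
            dof_names=list(data.dof_names),
            channel_names=list(data.channel_names),
            val_history=history,
        )


def train_angle_regressor(
    data: AlignedDataset,
    config: RegressorConfig | None = None,
    **fit_kwargs,
) -> AngleRegressionResults:
    """Functional wrapper around :class:`AngleRegressor`."""
    return AngleRegressor(config).fit(data, **fit_kwargs)


def evaluate_regressor(results: AngleRegressionResults, data: AlignedDataset,
                       tag: str | None = "test") -> CalibReport:
    """Functional wrapper around :meth:`AngleRegressionResults.evaluate`."""
    return results.evaluate(data, tag=tag)


def drift_baseline(
    values: np.ndarray,
    window: int = 18_000,
    passes: int = 2,
    polyorder: int = 3,
    edge_mode: str = "nearest",
) -> np.ndarray:
    """Slow per-channel baseline: Savitzky-Golay smoothing applied ``passes`` times.

    The window is forced odd (rounded up) and clipped to the stream length;
    polynomial order 3 preserves constants and ramps exactly.
    """
    x = np.atleast_2d(np.asarray(values, float).T).T
    if len(x) <= polyorder:
        raise ContractError("stream too short for the baseline filter")
    w = min(window, len(x))
    if w % 2 == 0:
        w += 1 if w < len(x) else -1
    w = max(w, polyorder + 2 if (polyorder + 2) % 2 == 1 else polyorder + 3)
    out = x
    for _ in range(passes):
        out = savgol_filter(out, window_length=w, polyorder=polyorder, axis=0, mode=edge_mode)
    return out.reshape(np.shape(values))
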