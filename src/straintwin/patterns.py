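"""Frequency-domain motion profiling and LSTM motion-pattern classification.

Periodic motions (reaches, gait) are complex in the time domain but clean in
the frequency domain: the DC bin captures the stationary pose offset of a
recording and the dominant non-DC components capture movement frequency and
amplitude.  Sequential pattern classification uses a 3-layer hidden-50 LSTM
over short look-back windows (default one step) with a linear softmax head,
trained with cross-entropy and Adam on a per-class sequential 3:1:1 split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lstm import LSTMCore
from .errors import ContractError
from .preprocess import AlignedDataset


# ---------------------------------------------------------------------------
# spectra


@dataclass
class Spectrum:
    """One-sided amplitude spectrum with the DC offset reported separately."""

    frequencies: np.ndarray  # (nf,) Hz, DC excluded
    amplitudes: np.ndarray  # (nf,) or (nf, C) sinusoid amplitudes
    offset: np.ndarray  # () or (C,): the DC (stationary pose) component
    n_samples: int
    rate: float

    def dominant(self, k: int = 3) -> list[tuple[float, float]]:
        """Top-k (frequency, amplitude) pairs, DC excluded, amplitude order."""
        amp = self.amplitudes if self.amplitudes.ndim == 1 else self.amplitudes.sum(axis=1)
        order = np.argsort(amp)[::-1][:k]
        return [(float(self.frequencies[i]), float(amp[i])) for i in order]

    def mean_square(self) -> np.ndarray:
        """Time-domain mean square reconstructed from the spectrum (Parseval)."""
        n = self.n_samples
        amp2 = self.amplitudes ** 2
        # non-DC bins carry amp^2/2 except an even-length Nyquist bin (amp^2/4
        # because its amplitude was doubled like an interior bin)
        ms = self.offset ** 2 + amp2.sum(axis=0) / 2.0
        if n % 2 == 0:
            ms -= amp2[-1] / 4.0
        return ms

    def to_csv(self, path, channel_names=None) -> None:
        amps = np.atleast_2d(self.amplitudes.T).T
        cols = channel_names or [f"amp{c:02d}" for c in range(amps.shape[1])]
        df = pd.DataFrame(amps, columns=cols)
        df.insert(0, "frequency_hz", self.frequencies)
        df.to_csv(path, index=False)


def frequency_profile(series: np.ndarray, rate: float,
                      times: np.ndarray | None = None) -> Spectrum:
    """Magnitude spectrum of a uniformly sampled series (frames or frames x C).

    The DC bin is reported as the stationary offset; ``dominant`` components
    exclude it.  Raises on non-uniform timestamps.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 16:
        raise ContractError("need at least 16 frames for a spectrum")
    if times is not None:
        dt = np.diff(np.asarray(times, float))
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ContractError("timestamps must be uniform")
        rate = 1.0 / float(dt.mean())
    X = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mag = np.abs(X) / n
    amps = 2.0 * mag
    offset = mag[0]  # DC: |X0|/n = mean
    return Spectrum(
        frequencies=freqs[1:],
        amplitudes=amps[1:],
        offset=offset,
        n_samples=n,
        rate=rate,
    )


# ---------------------------------------------------------------------------
# windowing


def make_windows(
    dataset: AlignedDataset,
    lookback: int = 1,
    split_tag: str | None = None,
    class_set: list[str] | None = None,
):
    """Look-back windows over contiguous labeled runs.

    A sample at frame t is frames [t-L+1 .. t] with t's label; the first L-1
    frames of each contiguous run are dropped and windows never span a label,
    split, or recording-gap boundary.  Returns (X (N, L, C), y (N,), classes).
    """
    if lookback < 1:
        raise ContractError("lookback must be >= 1")
    if dataset.labels is None:
        raise ContractError("windowing requires labels")
    labels = dataset.labels
    mask = np.array([lab is not None for lab in labels])
    if split_tag is not None:
        mask &= dataset.mask(split_tag)

    if class_set is None:
        class_set = sorted({str(l) for l in labels[mask]})
    cls_index = {c: k for k, c in enumerate(class_set)}

    # contiguous runs: same label, same split tag, consecutive frame index,
    # uniform time step
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return (np.empty((0, lookback, dataset.sensors.shape[1])), np.empty(0, dtype=int), class_set)
    dt = np.median(np.diff(dataset.times)) if len(dataset.times) > 1 else 0.0
    brk = np.nonzero(
        (np.diff(idx) != 1)
        | (labels[idx[1:]] != labels[idx[:-1]])
        | (np.abs(np.diff(dataset.times[idx]) - dt) > 0.5 * dt)
    )[0]
    starts = np.concatenate([[0], brk + 1])
    stops = np.concatenate([brk + 1, [len(idx)]])

    xs, ys = [], []
    L = lookback
    for s0, s1 in zip(starts, stops):
        run = idx[s0:s1]
        if len(run) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(
            dataset.sensors[run], (L, dataset.sensors.shape[1])
        )[:, 0]
        xs.append(windows)
        ys.append(np.array([cls_index[str(labels[t])] for t in run[L - 1:]]))
    if not xs:
        return (np.empty((0, L, dataset.sensors.shape[1])), np.empty(0, dtype=int), class_set)
    return np.concatenate(xs), np.concatenate(ys), class_set


# ---------------------------------------------------------------------------
# classifier model / results


@dataclass
class ClassifierConfig:
    """Hyperparameters of the sequence classifier (defaults match the
    reference recipe: 3 LSTM layers, hidden 50, one look-back step, Adam
    1e-3/eps 1e-4, batch 64, 1000 iterations)."""

    layers: int = 3
    hidden: int = 50
    lookback: int = 1
    learning_rate: float = 1e-3
    epsilon: float = 1e-4
    batch: int = 64
    iterations: int = 1000
    eval_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.lookback < 1:
            raise ContractError("lookback must be >= 1")
        for name in ("layers", "hidden", "learning_rate", "epsilon", "batch", "iterations"):
            if getattr(self, name) <= 0:
                raise ContractError(f"config field {name} must be positive")


class ClassificationResults:
    """Fit results: trained LSTM, class vocabulary and evaluation helpers."""

    def __init__(self, core: LSTMCore, config: ClassifierConfig, class_set,
                 channel_mean, channel_std, val_history):
        self._core = core
        self.config = config
        self.class_set = list(class_set)
        self.channel_mean = channel_mean
        self.channel_std = channel_std
        self.val_history = val_history

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.channel_mean) / self.channel_std

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) for raw windows (N, L, C)."""
        return self._core.predict_proba(self._standardize(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, data_or_windows, tag: str = "test"):
        """Accuracy and confusion matrix on held-out windows.

        Accepts an AlignedDataset (windows built from `tag` frames) or a
        pre-built (X, y) pair.  Returns (accuracy, confusion DataFrame) with
        confusion rows = true classes, columns = predicted.
        """
        if isinstance(data_or_windows, AlignedDataset):
            X, y, _ = make_windows(
                data_or_windows, self.config.lookback, split_tag=tag, class_set=self.class_set
            )
        else:
            X, y = data_or_windows
        pred = self.predict(X)
        K = len(self.class_set)
        conf = np.zeros((K, K), dtype=int)
        np.add.at(conf, (y, pred), 1)
        acc = float((pred == y).mean()) if len(y) else float("nan")
        return acc, pd.DataFrame(conf, index=self.class_set, columns=self.class_set)

    def per_class_accuracy(self, confusion: pd.DataFrame) -> dict[str, float]:
        diag = np.diag(confusion.to_numpy())
        totals = confusion.to_numpy().sum(axis=1)
        return {
            c: (float(d) / t if t else float("nan"))
            for c, d, t in zip(self.class_set, diag, totals)
        }

    def summary(self, accuracy: float | None = None) -> str:
        lines = [
            "Motion-pattern classification results",
            "=====================================",
            f"architecture : {self.config.layers}-layer LSTM, hidden {self.config.hidden}, "
            f"softmax head over {len(self.class_set)} classes",
            f"look-back    : {self.config.lookback} step(s)",
            f"training     : {self.config.iterations} Adam steps, batch {self.config.batch}",
            f"best val CE  : {min(m for _, m in self.val_history):.4f}",
        ]
        if accuracy is not None:
            lines.append(f"test accuracy: {accuracy:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self._core.params)}
        np.savez(
            path,
            channel_mean=self.channel_mean,
            channel_std=self.channel_std,
            config=json.dumps(self.config.__dict__),
            class_set=json.dumps(self.class_set),
            **arrays,
        )


class MotionClassifier:
    """Model object: configure, then :meth:`fit` on a labeled, split dataset."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()

    def fit(self, data: AlignedDataset) -> ClassificationResults:
        cfg = self.config
        x_tr, y_tr, class_set = make_windows(data, cfg.lookback, split_tag="train")
        x_va, y_va, _ = make_windows(data, cfg.lookback, split_tag="val", class_set=class_set)
        if len(class_set) < 2:
            raise ContractError("need at least two classes")
        mean = x_tr.reshape(-1, x_tr.shape[-1]).mean(axis=0)
        std = np.maximum(x_tr.reshape(-1, x_tr.shape[-1]).std(axis=0), 1e-8)
        x_tr = (x_tr - mean) / std
        x_va = (x_va - mean) / std
        core = LSTMCore(
            input_dim=x_tr.shape[-1],
            n_classes=len(class_set),
            layers=cfg.layers,
            hidden=cfg.hidden,
            lr=cfg.learning_rate,
            eps=cfg.epsilon,
            seed=cfg.seed,
        )
        history = core.fit(
            x_tr, y_tr, x_va, y_va,
            iterations=cfg.iterations, batch=cfg.batch,
            eval_every=cfg.eval_every, seed=cfg.seed,
        )
        return ClassificationResults(
            core=core, config=cfg, class_set=class_set,
            channel_mean=mean, channel_std=std, val_history=history,
        )


def train_motion_classifier(data: AlignedDataset,
                            config: ClassifierConfig | None = None) -> ClassificationResults:
    """Functional wrapper around :class:`MotionClassifier`."""
    return MotionClassifier(config).fit(data)


def evaluate_classifier(results: ClassificationResults, data: AlignedDataset,
                        tag: str = "test"):
    """Functional wrapper around :meth:`ClassificationResults.evaluate`."""
    return results.evaluate(data, tag=tag)
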