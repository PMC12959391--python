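"""Minimal stacked-LSTM sequence classifier in numpy.

Three LSTM layers (hidden size 50 by default), one fully connected head and a
softmax, trained with cross-entropy and Adam.  Sequences are short look-back
windows (often a single step), so plain backpropagation-through-time in numpy
is fast enough; gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import ContractError


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTMCore:
    """Stacked LSTM + linear softmax head with Adam training."""

    def __init__(self, input_dim: int, n_classes: int, layers: int = 3,
                 hidden: int = 50, lr: float = 1e-3, eps: float = 1e-4,
                 seed: int = 0):
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.layers = layers
        self.hidden = hidden
        self.lr = lr
        self.eps = eps
        rng = np.random.default_rng(seed)
        H = hidden
        self.params: list[np.ndarray] = []
        for l in range(layers):
            d_in = input_dim if l == 0 else H
            k = 1.0 / np.sqrt(H)
            self.params.append(rng.uniform(-k, k, size=(4 * H, d_in)))  # Wx
            self.params.append(rng.uniform(-k, k, size=(4 * H, H)))  # Wh
            self.params.append(rng.uniform(-k, k, size=4 * H))  # b
        k = 1.0 / np.sqrt(H)
        self.params.append(rng.uniform(-k, k, size=(n_classes, H)))  # Wf
        self.params.append(rng.uniform(-k, k, size=n_classes))  # bf
        self._adam_m = [np.zeros_like(p) for p in self.params]
        self._adam_v = [np.zeros_like(p) for p in self.params]
        self._adam_t = 0

    # -- forward / backward ---------------------------------------------------

    def _layer_params(self, l):
        return self.params[3 * l], self.params[3 * l + 1], self.params[3 * l + 2]

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        """X (B, L, D) -> logits (B, K); optionally caches for backprop."""
        B, L, D = X.shape
        H = self.hidden
        h = [np.zeros((B, H)) for _ in range(self.layers)]
        c = [np.zeros((B, H)) for _ in range(self.layers)]
        cache = [] if keep_cache else None
        for t in range(L):
            x = X[:, t]
            step_cache = [] if keep_cache else None
            for l in range(self.layers):
                Wx, Wh, b = self._layer_params(l)
                z = x @ Wx.T + h[l] @ Wh.T + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H: 2 * H])
                g = np.tanh(z[:, 2 * H: 3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c[l] + i * g
                h_new = o * np.tanh(c_new)
                if keep_cache:
                    step_cache.append((x, h[l], c[l], i, f, g, o, c_new))
                h[l], c[l] = h_new, c_new
                x = h_new
            if keep_cache:
                cache.append(step_cache)
        Wf, bf = self.params[-2], self.params[-1]
        logits = h[-1] @ Wf.T + bf
        return (logits, h[-1], cache) if keep_cache else logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients w.r.t. every parameter."""
        B, L, _ = X.shape
        H = self.hidden
        logits, h_last, cache = self._forward(X, keep_cache=True)
        probs = self._softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))

        grads = [np.zeros_like(p) for p in self.params]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        Wf = self.params[-2]
        grads[-2] = dlogits.T @ h_last
        grads[-1] = dlogits.sum(axis=0)

        dh_next = [np.zeros((B, H)) for _ in range(self.layers)]
        dc_next = [np.zeros((B, H)) for _ in range(self.layers)]
        for t in range(L - 1, -1, -1):
            dx_above = dlogits @ Wf if t == L - 1 else np.zeros((B, H))
            for l in range(self.layers - 1, -1, -1):
                x, h_prev, c_prev, i, f, g, o, c_new = cache[t][l]
                dh = dh_next[l] + dx_above
                tanh_c = np.tanh(c_new)
                do = dh * tanh_c
                dc = dc_next[l] + dh * o * (1 - tanh_c ** 2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                    axis=1,
                )
                Wx, Wh, _ = self._layer_params(l)
                grads[3 * l] += dz.T @ x
                grads[3 * l + 1] += dz.T @ h_prev
                grads[3 * l + 2] += dz.sum(axis=0)
                dx_above = dz @ Wx  # flows into the layer below (or the input)
                dh_next[l] = dz @ Wh
                dc_next[l] = dc * f
        return loss, grads

    def adam_step(self, grads) -> None:
        self._adam_t += 1
        b1, b2 = 0.9, 0.999
        t = self._adam_t
        for p, g, m, v in zip(self.params, grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # -- training / inference --------------------------------------------------

    def fit(self, x_train, y_train, x_val, y_val, iterations: int = 1000,
            batch: int = 64, eval_every: int = 100, seed: int = 0):
        """Minibatch Adam training with a best-validation-loss snapshot."""
        if len(np.unique(y_train)) < 2:
            raise ContractError("need at least two classes to train a classifier")
        rng = np.random.default_rng(seed)
        best = None
        history = []
        for step in range(1, iterations + 1):
            idx = rng.integers(0, len(x_train), size=batch)
            loss, grads = self.loss_and_grads(x_train[idx], y_train[idx])
            self.adam_step(grads)
            if step % eval_every == 0 or step == iterations:
                val_loss = self.loss_on(x_val, y_val)
                history.append((step, val_loss))
                if best is None or val_loss < best[0]:
                    best = (val_loss, copy.deepcopy(self.params))
        self.params = best[1]
        return history

    def loss_on(self, X, y, chunk: int = 8192) -> float:
        total, n = 0.0, 0
        for i in range(0, len(X), chunk):
            p = self._softmax(self._forward(X[i: i + chunk]))
            yy = y[i: i + chunk]
            total += float(-np.sum(np.log(p[np.arange(len(yy)), yy] + 1e-12)))
            n += len(yy)
        return total / max(n, 1)

    def predict_proba(self, X: np.ndarray, chunk: int = 8192) -> np.ndarray:
        out = np.empty((len(X), self.n_classes))
        for i in range(0, len(X), chunk):
            out[i: i + chunk] = self._softmax(self._forward(X[i: i + chunk]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
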