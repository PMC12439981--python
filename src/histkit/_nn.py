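"""Minimal NumPy neural-network core for the dual-branch tail classifier.

Two 1D convolutional branches (one per input encoding) with ReLU and global
max pooling feed a concatenated fully connected head ending in a single
logit.  Forward, backward and Adam are written directly in NumPy so training
is exactly reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class DualBranchConvNet:
    """conv(K=5, C=128) -> ReLU -> global max, per branch; concat -> FC head."""

    def __init__(
        self,
        d_onehot: int,
        d_embed: int,
        hidden_channels: int = 128,
        kernel_size: int = 5,
        head_hidden: int = 64,
        seed: int = 0,
    ) -> None:
        self.d_onehot = d_onehot
        self.d_embed = d_embed
        self.C = hidden_channels
        self.K = kernel_size
        self.head_hidden = head_hidden
        rng = np.random.default_rng(seed)
        C, K = self.C, self.K
        self.params = {
            "Wc1": _he(rng, (K * d_onehot, C), K * d_onehot),
            "bc1": np.zeros(C),
            "Wc2": _he(rng, (K * d_embed, C), K * d_embed),
            "bc2": np.zeros(C),
            "W1": _he(rng, (2 * C, head_hidden), 2 * C),
            "b1": np.zeros(head_hidden),
            "w2": _he(rng, (head_hidden,), head_hidden),
            "b2": np.zeros(1),
        }

    @staticmethod
    def _windows(X: np.ndarray, K: int) -> np.ndarray:
        # (N, L, D) -> (N, L-K+1, K*D)
        win = sliding_window_view(X, K, axis=1)  # (N, Lout, D, K)
        win = np.swapaxes(win, 2, 3)  # (N, Lout, K, D)
        n, lout = win.shape[:2]
        return np.ascontiguousarray(win).reshape(n, lout, -1)

    def _branch_forward(self, X, W, b):
        win = self._windows(X, self.K)
        Z = win @ W + b
        A = np.maximum(Z, 0.0)
        amax = A.argmax(axis=1)  # (N, C)
        pooled = np.take_along_axis(A, amax[:, None, :], axis=1)[:, 0, :]
        return pooled, (win, Z, amax)

    def forward(self, X1: np.ndarray, X2: np.ndarray):
        p = self.params
        P1, c1 = self._branch_forward(X1, p["Wc1"], p["bc1"])
        P2, c2 = self._branch_forward(X2, p["Wc2"], p["bc2"])
        h = np.hstack([P1, P2])
        H1 = np.maximum(h @ p["W1"] + p["b1"], 0.0)
        logits = H1 @ p["w2"] + p["b2"][0]
        cache = (c1, c2, h, H1)
        return logits, cache

    def _branch_backward(self, cache, dP, W):
        win, Z, amax = cache
        dA = np.zeros_like(Z)
        np.put_along_axis(dA, amax[:, None, :], dP[:, None, :], axis=1)
        dZ = dA * (Z > 0)
        n, lout, kd = win.shape
        dW = win.reshape(n * lout, kd).T @ dZ.reshape(n * lout, -1)
        db = dZ.sum(axis=(0, 1))
        return dW, db

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        c1, c2, h, H1 = cache
        grads: dict[str, np.ndarray] = {}
        grads["w2"] = H1.T @ dlogits
        grads["b2"] = np.array([dlogits.sum()])
        dH1 = dlogits[:, None] * p["w2"][None, :] * (H1 > 0)
        grads["W1"] = h.T @ dH1
        grads["b1"] = dH1.sum(axis=0)
        dh = dH1 @ p["W1"].T
        dP1, dP2 = dh[:, : self.C], dh[:, self.C :]
        grads["Wc1"], grads["bc1"] = self._branch_backward(c1, dP1, p["Wc1"])
        grads["Wc2"], grads["bc2"] = self._branch_backward(c2, dP2, p["Wc2"])
        return grads

    def predict_logits(self, X1: np.ndarray, X2: np.ndarray, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, X1.shape[0], batch):
            logits, _ = self.forward(X1[i : i + batch], X2[i : i + batch])
            out.append(logits)
        return np.concatenate(out) if out else np.empty(0)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64)


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def weighted_bce_grad(
    logits: np.ndarray, y: np.ndarray, w: np.ndarray, pos_weight: float
) -> tuple[float, np.ndarray]:
    """Weighted BCE-with-logits loss (mean over total weight) and d/dlogits."""
    p = sigmoid(logits)
    # log-sum-exp stable per-term losses
    softplus = np.logaddexp(0.0, -np.abs(logits))
    log_p = np.where(logits >= 0, -softplus, logits - softplus)
    log_1mp = np.where(logits >= 0, -logits - softplus, -softplus)
    per = -(pos_weight * y * log_p + (1.0 - y) * log_1mp)
    wsum = w.sum()
    loss = float((w * per).sum() / wsum)
    dlogits = w * (p * (1.0 + (pos_weight - 1.0) * y) - pos_weight * y) / wsum
    return loss, dlogits
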