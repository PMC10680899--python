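"""Minimal NumPy neural-network primitives shared by the two models.

Implements exactly what the models need — a batched gated recurrent unit
(GRU) with hand-written backpropagation through time, dense layers, masked
softmax, and an Adam optimizer — with every gradient verified against
finite differences in the test suite.  Arrays are float64 throughout so
training is bit-reproducible for a fixed seed on any platform.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def masked_softmax(scores: np.ndarray, mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Softmax over *axis* with padded positions (mask==0) forced to 0."""
    s = np.where(mask > 0, scores, -np.inf)
    s = s - np.max(s, axis=axis, keepdims=True)
    e = np.exp(s)
    e = np.where(mask > 0, e, 0.0)
    return e / np.sum(e, axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def gru_init(rng: np.random.Generator, in_dim: int, hid_dim: int, prefix: str) -> dict:
    p = {}
    for gate in ("z", "r", "h"):
        p[f"{prefix}W{gate}"] = glorot(rng, (in_dim, hid_dim))
        p[f"{prefix}U{gate}"] = glorot(rng, (hid_dim, hid_dim))
        p[f"{prefix}b{gate}"] = np.zeros(hid_dim)
    return p


def gru_forward(
    X: np.ndarray, mask: np.ndarray, params: dict, prefix: str
) -> tuple[np.ndarray, dict]:
    """Run a GRU over a padded batch.

    X: (T, B, in_dim); mask: (T, B) with 1 for real steps.  Padded steps
    carry the previous hidden state through unchanged.  Returns hidden
    states H (T, B, hid) and a cache for the backward pass.
    """
    T, B, _ = X.shape
    hid = params[f"{prefix}bz"].shape[0]
    h = np.zeros((B, hid))
    H = np.zeros((T, B, hid))
    cache = {"X": X, "mask": mask, "steps": []}
    Wz, Uz, bz = params[f"{prefix}Wz"], params[f"{prefix}Uz"], params[f"{prefix}bz"]
    Wr, Ur, br = params[f"{prefix}Wr"], params[f"{prefix}Ur"], params[f"{prefix}br"]
    Wh, Uh, bh = params[f"{prefix}Wh"], params[f"{prefix}Uh"], params[f"{prefix}bh"]
    for t in range(T):
        x = X[t]
        z = sigmoid(x @ Wz + h @ Uz + bz)
        r = sigmoid(x @ Wr + h @ Ur + br)
        rh = r * h
        hh = np.tanh(x @ Wh + rh @ Uh + bh)
        h_new = (1.0 - z) * h + z * hh
        m = mask[t][:, None]
        h_next = m * h_new + (1.0 - m) * h
        cache["steps"].append((x, h, z, r, rh, hh))
        H[t] = h_next
        h = h_next
    return H, cache


def gru_backward(
    dH: np.ndarray, cache: dict, params: dict, prefix: str
) -> tuple[np.ndarray, dict]:
    """Backprop through time; returns (dX, dparams)."""
    X, mask = cache["X"], cache["mask"]
    T, B, in_dim = X.shape
    hid = params[f"{prefix}bz"].shape[0]
    Wz, Uz = params[f"{prefix}Wz"], params[f"{prefix}Uz"]
    Wr, Ur = params[f"{prefix}Wr"], params[f"{prefix}Ur"]
    Wh, Uh = params[f"{prefix}Wh"], params[f"{prefix}Uh"]
    grads = {k: np.zeros_like(params[k]) for k in params if k.startswith(prefix)}
    dX = np.zeros_like(X)
    dh = np.zeros((B, hid))
    for t in range(T - 1, -1, -1):
        x, h_prev, z, r, rh, hh = cache["steps"][t]
        m = mask[t][:, None]
        d = dH[t] + dh
        dh_pass = (1.0 - m) * d  # padded steps: gradient flows straight back
        d = m * d
        dhh = d * z
        dz = d * (hh - h_prev)
        dh_prev = d * (1.0 - z)
        da_h = dhh * (1.0 - hh * hh)
        grads[f"{prefix}Wh"] += x.T @ da_h
        grads[f"{prefix}Uh"] += rh.T @ da_h
        grads[f"{prefix}bh"] += da_h.sum(axis=0)
        drh = da_h @ Uh.T
        dr = drh * h_prev
        dh_prev += drh * r
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        grads[f"{prefix}Wz"] += x.T @ da_z
        grads[f"{prefix}Uz"] += h_prev.T @ da_z
        grads[f"{prefix}bz"] += da_z.sum(axis=0)
        grads[f"{prefix}Wr"] += x.T @ da_r
        grads[f"{prefix}Ur"] += h_prev.T @ da_r
        grads[f"{prefix}br"] += da_r.sum(axis=0)
        dX[t] = (da_z @ Wz.T + da_r @ Wr.T + da_h @ Wh.T) * m
        dh = dh_prev + da_z @ Uz.T + da_r @ Ur.T + dh_pass
    return dX, grads


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean weighted cross-entropy over a batch.

    logits: (B, C); y: (B,) int labels.  Returns (loss, dlogits, probs).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    B = len(y)
    w = np.ones(B) if sample_weight is None else sample_weight
    nll = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None))
    loss = float(np.sum(w * nll) / np.sum(w))
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / np.sum(w))[:, None]
    return loss, dlogits, probs


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
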