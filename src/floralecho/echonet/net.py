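"""A compact numpy convolutional network for echo-chunk classification.

Architecture: each of the k echo spectrograms in a chunk passes through a
shared-weight branch (conv 16 channels, 3x3, stride 1 -> ReLU -> max pool
3x3, stride 2); the k branch outputs are concatenated along the channel axis
and processed by a trunk (conv 32 channels, 3x3 -> ReLU -> max pool 3x3,
stride 2), followed by three dense layers (256, 128, n_classes) and a softmax
over the species classes. Training uses cross-entropy loss with the Adam
optimizer. Everything is plain numpy (im2col-style convolutions via strided
views), deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["EchoCNN", "Adam", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layer primitives (valid padding throughout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray):
    """(N,C,H,W) -> (N, C*9, Ho*Wo) patch matrix for a 3x3 valid conv."""
    n, c, h, w = x.shape
    ho, wo = h - 2, w - 2
    cols = np.empty((n, c, 9, ho * wo), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            cols[:, :, u * 3 + v, :] = x[:, :, u : u + ho, v : v + wo].reshape(
                n, c, ho * wo
            )
    return cols.reshape(n, c * 9, ho * wo)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (N,C,H,W), W (F,C,3,3) -> out (N,F,H-2,W-2); batched BLAS matmul."""
    n, c, h, w = x.shape
    ho, wo = h - 2, w - 2
    cols = _im2col(x)
    wmat = W.reshape(W.shape[0], c * 9)
    out = np.matmul(wmat, cols).reshape(n, -1, ho, wo) + b[None, :, None, None]
    return out, (x.shape, cols)


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    x_shape, cols = cache
    n, c, h, w = x_shape
    f = W.shape[0]
    ho, wo = dout.shape[2], dout.shape[3]
    doutm = dout.reshape(n, f, ho * wo)
    dW = np.matmul(doutm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    wmat = W.reshape(f, c * 9)
    dcols = np.matmul(wmat.T, doutm).reshape(n, c, 9, ho * wo)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for u in range(3):
        for v in range(3):
            dx[:, :, u : u + ho, v : v + wo] += dcols[:, :, u * 3 + v, :].reshape(
                n, c, ho, wo
            )
    return dx, dW, db


def _pool_forward(x: np.ndarray, size: int = 3, stride: int = 2):
    """Max pool (N,C,H,W) -> (N,C,Ho,Wo) with argmax cache for backprop."""
    win = sliding_window_view(x, (size, size), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, size * size)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, (x.shape, arg, size, stride)


def _pool_backward(dout: np.ndarray, cache):
    x_shape, arg, size, stride = cache
    n, c, ho, wo = dout.shape
    _, _, h, w = x_shape
    ni, ci, ii, ji = np.ogrid[:n, :c, :ho, :wo]
    rows = ii * stride + arg // size
    cols = ji * stride + arg % size
    flat = ((np.broadcast_to(ni, arg.shape) * c
             + np.broadcast_to(ci, arg.shape)) * h + rows) * w + cols
    dx = np.bincount(
        flat.ravel(), weights=dout.ravel(), minlength=n * c * h * w
    )
    return dx.reshape(x_shape).astype(dout.dtype, copy=False)


def _pool_out(n: int, size: int = 3, stride: int = 2) -> int:
    return (n - size) // stride + 1


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / b1t
            vhat = self.v[name] / b2t
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EchoCNN:
    """Multi-input CNN with a weight-shared per-echo branch.

    Parameters
    ----------
    input_shape:
        (freq_bins, frames) of one spectrogram.
    k:
        Number of echoes presented simultaneously (1, 3, 5, 7 or 10).
    """

    VALID_K = (1, 3, 5, 7, 10)

    def __init__(
        self,
        input_shape: Tuple[int, int],
        k: int,
        n_classes: int = 12,
        branch_channels: int = 16,
        trunk_channels: int = 32,
        dense_sizes: Tuple[int, int] = (256, 128),
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if k not in self.VALID_K:
            raise ValueError(f"k must be one of {self.VALID_K}, got {k}")
        h, w = input_shape
        if h < 7 or w < 7:
            raise ValueError(f"spectrogram {input_shape} too small for two conv/pool stages")
        self.input_shape = input_shape
        self.k = k
        self.n_classes = n_classes
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(self.dtype)

        h1, w1 = h - 2, w - 2
        h1p, w1p = _pool_out(h1), _pool_out(w1)
        h2, w2 = h1p - 2, w1p - 2
        h2p, w2p = _pool_out(h2), _pool_out(w2)
        if min(h2, w2, h2p, w2p) < 1:
            raise ValueError(f"spectrogram {input_shape} too small for the trunk")
        flat = trunk_channels * h2p * w2p
        self._branch_out = (h1p, w1p)
        self.params: Dict[str, np.ndarray] = {
            "W_branch": he((branch_channels, 1, 3, 3), 9),
            "b_branch": np.zeros(branch_channels, dtype=self.dtype),
            "W_trunk": he((trunk_channels, branch_channels * k, 3, 3),
                          9 * branch_channels * k),
            "b_trunk": np.zeros(trunk_channels, dtype=self.dtype),
            "W_d1": he((flat, dense_sizes[0]), flat),
            "b_d1": np.zeros(dense_sizes[0], dtype=self.dtype),
            "W_d2": he((dense_sizes[0], dense_sizes[1]), dense_sizes[0]),
            "b_d2": np.zeros(dense_sizes[1], dtype=self.dtype),
            "W_out": he((dense_sizes[1], n_classes), dense_sizes[1]),
            "b_out": np.zeros(n_classes, dtype=self.dtype),
        }

    @property
    def n_branch_params(self) -> int:
        """Parameter count of the shared per-echo branch (independent of k)."""
        return self.params["W_branch"].size + self.params["b_branch"].size

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray):
        """x (N, k, H, W) -> probs (N, n_classes) plus caches."""
        if x.ndim != 4 or x.shape[1] != self.k or x.shape[2:] != self.input_shape:
            raise ValueError(
                f"expected input (N, {self.k}, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}"
            )
        p = self.params
        n = x.shape[0]
        x = np.asarray(x, dtype=self.dtype)
        xb = x.reshape(n * self.k, 1, *self.input_shape)
        c1, cache_c1 = _conv_forward(xb, p["W_branch"], p["b_branch"])
        r1 = np.maximum(c1, 0.0)
        p1, cache_p1 = _pool_forward(r1)
        # concatenate the k branch outputs along the channel axis
        concat = p1.reshape(n, self.k * p1.shape[1], *p1.shape[2:])
        c2, cache_c2 = _conv_forward(concat, p["W_trunk"], p["b_trunk"])
        r2 = np.maximum(c2, 0.0)
        p2, cache_p2 = _pool_forward(r2)
        flat = p2.reshape(n, -1)
        d1 = flat @ p["W_d1"] + p["b_d1"]
        a1 = np.maximum(d1, 0.0)
        d2 = a1 @ p["W_d2"] + p["b_d2"]
        a2 = np.maximum(d2, 0.0)
        logits = a2 @ p["W_out"] + p["b_out"]
        probs = softmax(logits.astype(np.float64))
        cache = (xb, cache_c1, c1, cache_p1, p1, concat, cache_c2, c2,
                 cache_p2, p2, flat, d1, a1, d2, a2)
        return probs, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self._forward(x[i : i + batch_size])[0]
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and gradients for a labelled batch."""
        p = self.params
        n = x.shape[0]
        probs, cache = self._forward(x)
        (xb, cache_c1, c1, cache_p1, p1, concat, cache_c2, c2,
         cache_p2, p2, flat, d1, a1, d2, a2) = cache
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), y] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dlogits = dlogits.astype(self.dtype)
        grads: Dict[str, np.ndarray] = {}
        grads["W_out"] = a2.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        da2 = dlogits @ p["W_out"].T
        dd2 = da2 * (d2 > 0)
        grads["W_d2"] = a1.T @ dd2
        grads["b_d2"] = dd2.sum(axis=0)
        da1 = dd2 @ p["W_d2"].T
        dd1 = da1 * (d1 > 0)
        grads["W_d1"] = flat.T @ dd1
        grads["b_d1"] = dd1.sum(axis=0)
        dflat = dd1 @ p["W_d1"].T
        dp2 = dflat.reshape(p2.shape)
        dr2 = _pool_backward(dp2, cache_p2)
        dc2 = dr2 * (c2 > 0)
        dconcat, grads["W_trunk"], grads["b_trunk"] = _conv_backward(
            dc2, p["W_trunk"], cache_c2
        )
        dp1 = dconcat.reshape(p1.shape)
        dr1 = _pool_backward(dp1, cache_p1)
        dc1 = dr1 * (c1 > 0)
        _, grads["W_branch"], grads["b_branch"] = _conv_backward(
            dc1, p["W_branch"], cache_c1
        )
        return loss, grads, probs

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()

    def save(self, path) -> None:
        np.savez(path, k=self.k, n_classes=self.n_classes,
                 h=self.input_shape[0], w=self.input_shape[1], **self.params)

    @classmethod
    def load(cls, path) -> "EchoCNN":
        data = np.load(path)
        model = cls(
            (int(data["h"]), int(data["w"])), int(data["k"]),
            n_classes=int(data["n_classes"]),
            branch_channels=data["W_branch"].shape[0],
            trunk_channels=data["W_trunk"].shape[0],
            dense_sizes=(data["W_d1"].shape[1], data["W_d2"].shape[1]),
        )
        model.load_state_dict({k: data[k] for k in model.params})
        return model
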