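"""Minimal numpy neural-network core for the 1D-CNN classifier.

Implements exactly the pieces the gesture classifier needs — valid-mode 1D
convolution (via ``sliding_window_view`` + ``einsum``), ReLU, non-overlapping
max-pooling, dense layers, softmax cross-entropy, and the Adam optimizer —
with hand-derived backward passes. Everything is deterministic given the
initialization seed and the mini-batch order; there is no threading or
device nondeterminism.

Weights live in a flat ``dict[str, ndarray]`` state dict so artifacts can be
serialized as plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError

__all__ = ["ConvNet1D", "Adam", "softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss (nats) and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class ConvNet1D:
    """Two Conv1D->ReLU->maxpool blocks followed by five dense layers.

    Input: ``(batch, n_channels, window_len)``; output: ``(batch, n_classes)``
    logits. Convolutions are valid-mode, pooling is non-overlapping with
    truncation of the incomplete tail. ReLU sits between all layers except
    after the final dense layer.
    """

    def __init__(
        self,
        n_channels: int,
        window_len: int,
        conv_blocks: tuple[tuple[int, int, int], ...],
        dense_widths: tuple[int, ...],
        seed: int = 0,
    ):
        self.n_channels = int(n_channels)
        self.window_len = int(window_len)
        self.conv_blocks = tuple((int(f), int(k), int(p)) for f, k, p in conv_blocks)
        self.dense_widths = tuple(int(w) for w in dense_widths)

        # trace the temporal length through the conv stack
        length = self.window_len
        in_ch = self.n_channels
        for i, (filters, kernel, pool) in enumerate(self.conv_blocks):
            length = length - kernel + 1
            if length < 1:
                raise ConfigurationError(
                    f"window_len {window_len} too short for conv block {i}: "
                    f"needs at least {self._min_window_len()} samples"
                )
            length = length // pool
            if length < 1:
                raise ConfigurationError(
                    f"window_len {window_len} too short for pool {pool} in block {i}: "
                    f"needs at least {self._min_window_len()} samples"
                )
            in_ch = filters
        self.flat_dim = in_ch * length

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.params: dict[str, np.ndarray] = {}
        in_ch = self.n_channels
        for i, (filters, kernel, _) in enumerate(self.conv_blocks):
            fan_in = in_ch * kernel
            self.params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(filters, in_ch, kernel)
            )
            self.params[f"conv{i}_b"] = np.zeros(filters)
            in_ch = filters
        prev = self.flat_dim
        for j, width in enumerate(self.dense_widths):
            self.params[f"dense{j}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / prev), size=(prev, width)
            )
            self.params[f"dense{j}_b"] = np.zeros(width)
            prev = width

    def _min_window_len(self) -> int:
        # smallest window that leaves >= 1 sample after every conv+pool
        length = 1
        for filters, kernel, pool in reversed(self.conv_blocks):
            length = length * pool + kernel - 1
        return length

    @property
    def n_classes(self) -> int:
        return self.dense_widths[-1]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.n_channels or x.shape[2] != self.window_len:
            raise ShapeError(
                f"expected input (batch, {self.n_channels}, {self.window_len}), "
                f"got shape {x.shape}"
            )
        cache: dict = {"x": x}
        h = x
        for i, (filters, kernel, pool) in enumerate(self.conv_blocks):
            W, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            cols = np.lib.stride_tricks.sliding_window_view(h, kernel, axis=2)
            z = np.einsum("bclk,ock->bol", cols, W, optimize=True) + b[None, :, None]
            a = np.maximum(z, 0.0)
            lp = a.shape[2] // pool
            blocks = a[:, :, : lp * pool].reshape(a.shape[0], a.shape[1], lp, pool)
            arg = blocks.argmax(axis=3)
            pooled = np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]
            if want_cache:
                cache[f"conv{i}"] = (h, cols, z, a, arg, lp)
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        cache["pre_flat_shape"] = h.shape
        acts = [flat]
        for j in range(len(self.dense_widths)):
            W, b = self.params[f"dense{j}_W"], self.params[f"dense{j}_b"]
            z = acts[-1] @ W + b
            h_out = z if j == len(self.dense_widths) - 1 else np.maximum(z, 0.0)
            acts.append(h_out)
        cache["dense_acts"] = acts
        logits = acts[-1]
        return (logits, cache) if want_cache else logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        acts = cache["dense_acts"]
        d = dlogits
        for j in reversed(range(len(self.dense_widths))):
            a_in = acts[j]
            if j != len(self.dense_widths) - 1:
                d = d * (acts[j + 1] > 0)  # ReLU mask on the layer output
            grads[f"dense{j}_W"] = a_in.T @ d
            grads[f"dense{j}_b"] = d.sum(axis=0)
            d = d @ self.params[f"dense{j}_W"].T
        d = d.reshape(cache["pre_flat_shape"])
        for i in reversed(range(len(self.conv_blocks))):
            h_in, cols, z, a, arg, lp = cache[f"conv{i}"]
            _, kernel, pool = self.conv_blocks[i]
            # un-pool: route gradient to the argmax positions
            da = np.zeros_like(a)
            da_blocks = da[:, :, : lp * pool].reshape(a.shape[0], a.shape[1], lp, pool)
            np.put_along_axis(da_blocks, arg[..., None], d[..., None], axis=3)
            dz = da * (z > 0)
            W = self.params[f"conv{i}_W"]
            grads[f"conv{i}_W"] = np.einsum("bclk,bol->ock", cols, dz, optimize=True)
            grads[f"conv{i}_b"] = dz.sum(axis=(0, 2))
            dh = np.zeros_like(h_in)
            for k in range(kernel):
                # dz has length L-K+1 along time; each tap k scatters onto x[t+k]
                dh[:, :, k : k + dz.shape[2]] += np.einsum(
                    "bol,oc->bcl", dz, W[:, :, k], optimize=True
                )
            d = dh
        return grads

    # ---- weights ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise ShapeError(f"state dict missing parameter {k!r}")
            arr = np.asarray(state[k], dtype=float)
            if arr.shape != v.shape:
                raise ShapeError(
                    f"parameter {k!r}: expected shape {v.shape}, got {arr.shape}"
                )
            self.params[k] = arr.copy()


@dataclass
class Adam:
    """Adam optimizer over a named parameter dict (lr 0.001 by default)."""

    params: dict[str, np.ndarray]
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
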