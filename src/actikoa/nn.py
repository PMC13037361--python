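"""Minimal feed-forward building blocks with explicit reverse-mode gradients.

Implements exactly the layers the diurnal classifier needs — 1D same-padded
convolution, batch normalization, embeddings, dense layers, ReLU — together
with softmax cross-entropy and an Adam optimizer, all in numpy float64.
Every layer caches what its backward pass needs; gradients accumulate into
``Parameter.grad``. A finite-difference check in the test suite pins down
the analytic gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape)


class Conv1dSame:
    """1D convolution, stride 1, zero 'same' padding: length in = length out."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = Parameter(_uniform(rng, (out_ch, in_ch, kernel), bound), "conv.w")
        self.bias = Parameter(_uniform(rng, (out_ch,), bound), "conv.b")
        self.kernel = kernel
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, Cin, L = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        patches = sliding_window_view(xp, self.kernel, axis=2)  # (B, Cin, L, k)
        # im2col: contiguous (B*L, Cin*k) so the contraction is one matmul
        col = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(B * L, Cin * self.kernel)
        self._cache = (col, (B, Cin, L))
        out_ch = self.weight.data.shape[0]
        w2 = self.weight.data.reshape(out_ch, Cin * self.kernel)
        y = col @ w2.T + self.bias.data
        return y.reshape(B, L, out_ch).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, (B, Cin, L) = self._cache
        out_ch = grad.shape[1]
        k, pad = self.kernel, self.kernel // 2
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * L, out_ch)
        self.weight.grad += (g2.T @ col).reshape(out_ch, Cin, k)
        self.bias.grad += g2.sum(axis=0)
        dcol = (g2 @ self.weight.data.reshape(out_ch, Cin * k)).reshape(B, L, Cin, k)
        dpatch = dcol.transpose(0, 2, 1, 3)  # (B, Cin, L, k)
        dxp = np.zeros((B, Cin, L + 2 * pad))
        for kk in range(k):
            dxp[:, :, kk : kk + L] += dpatch[:, :, :, kk]
        return dxp[:, :, pad : pad + L]


class BatchNorm1d:
    """Per-channel normalization over batch and length, torch semantics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            n = x.shape[0] * x.shape[2]
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))  # biased, used for normalization
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.data[None, :, None]
        if not train:
            return dxhat * inv_std[None, :, None]
        n = grad.shape[0] * grad.shape[2]
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return inv_std[None, :, None] / n * (n * dxhat - s1 - xhat * s2)


class Embedding:
    """Dense vector per categorical level; rows selected by integer index."""

    def __init__(self, n_levels: int, dim: int, rng: np.random.Generator, name: str = "emb"):
        self.table = Parameter(rng.normal(0.0, 1.0, (n_levels, dim)), name)
        self.n_levels = n_levels
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.table]

    def forward(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_levels):
            raise ValueError(f"embedding index out of range 0..{self.n_levels - 1}")
        self._cache = idx
        return self.table.data[idx]

    def backward(self, grad: np.ndarray) -> None:
        np.add.at(self.table.grad, self._cache, grad)


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str = "fc"):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(_uniform(rng, (out_dim, in_dim), bound), f"{name}.w")
        self.bias = Parameter(_uniform(rng, (out_dim,), bound), f"{name}.b")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._cache
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adaptive moment estimation with the canonical defaults."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
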