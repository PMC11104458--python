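"""1-D convolutional layers with explicit forward/backward passes.

All layers operate on arrays of shape ``(N, C, T)`` (batch, channels, time) in
float64, cache whatever the backward pass needs, and expose ``params()`` /
``grads()`` as flat lists of arrays so one optimizer can drive any stack.
Gradient correctness is pinned by finite-difference tests; keep the math here
boring and exact rather than fast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ReLU", "GlobalAvgPool", "Dense", "Sequential", "Adam"]


def same_pad(kernel: int) -> tuple[int, int]:
    """Asymmetric 'same' padding: total k-1, split left-heavy like most frameworks."""
    return (kernel - 1) // 2, kernel // 2


def conv_out_len(t: int, kernel: int, stride: int) -> int:
    # with same_pad the padded length is t + k - 1, so:
    return (t - 1) // stride + 1


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Cross-correlation along time with 'same' padding and integer stride.

    Weight shape ``(c_out, c_in, k)``. He-normal weight init; biases get a small
    random perturbation so that architecturally identical but independently
    initialised layers respond differently even to an all-zero input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        rng = rng if rng is not None else np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = rng.normal(0.0, 0.05, size=c_out)
        self.stride = stride
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def kernel(self) -> int:
        return self.w.shape[2]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c_in, t = x.shape
        if c_in != self.w.shape[1]:
            raise ValueError(f"expected {self.w.shape[1]} input channels, got {c_in}")
        pl, pr = same_pad(self.kernel)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (N, C_in, T_out, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]
        y = np.einsum("nitk,oik->not", win, self.w, optimize=True)
        y += self.b[None, :, None]
        self._cache = (x.shape, win, xp.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, win, xp_shape = self._cache
        self.gw += np.einsum("not,nitk->oik", gy, win, optimize=True)
        self.gb += gy.sum(axis=(0, 2))
        n, _, t = x_shape
        pl, _ = same_pad(self.kernel)
        t_out = gy.shape[2]
        gxp = np.zeros((n, self.w.shape[1], xp_shape[2]))
        # scatter gy through each kernel tap
        for j in range(self.kernel):
            contrib = np.einsum("not,oi->nit", gy, self.w[:, :, j], optimize=True)
            gxp[:, :, j : j + self.stride * t_out : self.stride] += contrib
        return gxp[:, :, pl : pl + t]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class GlobalAvgPool(Layer):
    """Mean over the temporal axis: (N, C, T) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, :, None], self._t, axis=2) / self._t


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw += gy.T @ self._x
        self.gb += gy.sum(axis=0)
        return gy @ self.w


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Adam:
    """Plain Adam; operates in place on the param/grad lists of a layer stack."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
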