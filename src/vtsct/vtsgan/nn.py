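"""Minimal deterministic 3D conv-net building blocks in NumPy.

Forward/backward passes are hand-written; networks are tiny (a few
thousand parameters) because training runs on one CPU inside test
budgets.  All arrays are float32, NCDHW layout ``(batch, channel, x, y,
z)``; convolutions are stride-1 with zero "same" padding, implemented
via ``sliding_window_view`` + einsum, which is reproducible bit-for-bit
for a fixed input on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "Sequential", "Adam"]


class Conv3d:
    """Stride-1 'same' 3D convolution with bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int | tuple[int, int, int] = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        if isinstance(kernel, int):
            kernel = (kernel, kernel, kernel)
        kernel = tuple(int(k) for k in kernel)
        if any(k % 2 != 1 for k in kernel):
            raise ValueError("kernel sizes must be odd")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch) + kernel)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            fan_in = in_ch * int(np.prod(kernel))
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch) + kernel)
        self.w = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._x_pad: np.ndarray | None = None
        self.grads: dict[str, np.ndarray] = {}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def _pads(self) -> tuple:
        return ((0, 0), (0, 0)) + tuple((k // 2, k // 2) for k in self.kernel)

    @staticmethod
    def _im2col(xp: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
        """(N, C, Xp, Yp, Zp) -> (N*X*Y*Z, C*kx*ky*kz) patch matrix."""
        win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=(2, 3, 4))
        # win: (N, C, X, Y, Z, kx, ky, kz)
        n, c, x, y, z = win.shape[:5]
        return win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * x * y * z, -1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xp = np.pad(x, self._pads())
        if train:
            self._x_pad = xp
        N, C = x.shape[:2]
        sp = x.shape[2:]
        cols = self._im2col(xp, self.kernel)
        wmat = self.w.reshape(self.out_ch, -1)
        y = (cols @ wmat.T).reshape(N, *sp, self.out_ch)
        y = y.transpose(0, 4, 1, 2, 3) + self.b[None, :, None, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x_pad is not None, "forward(train=True) must precede backward"
        gb = gy.sum(axis=(0, 2, 3, 4))
        N = gy.shape[0]
        sp = gy.shape[2:]
        cols = self._im2col(self._x_pad, self.kernel)
        gymat = gy.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        gw = (gymat.T @ cols).reshape((self.out_ch, self.in_ch) + self.kernel)
        # input gradient = full correlation of gy with the flipped kernel
        gyp = np.pad(gy, self._pads())
        gcols = self._im2col(gyp, self.kernel)
        wf = self.w[:, :, ::-1, ::-1, ::-1]
        wmat = wf.transpose(0, 2, 3, 4, 1).reshape(-1, self.in_ch)
        gx = (gcols @ wmat).reshape(N, *sp, self.in_ch)
        gx = np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3), dtype=np.float32)
        self.grads = {"w": gw.astype(np.float32), "b": gb.astype(np.float32)}
        return gx


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None
        self.grads: dict[str, np.ndarray] = {}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def parameters(self) -> list[tuple[object, str]]:
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{i}.{name}"
                setattr(layer, name, np.asarray(arrays[key], dtype=np.float32))


class Adam:
    """Adam over a Sequential's parameters; state kept per-parameter."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.net = net
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {f"{i}.{n}": np.zeros_like(getattr(l, n))
                  for i, (l, n) in enumerate(net.parameters())}
        self.v = {k: np.zeros_like(a) for k, a in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, (layer, name) in enumerate(self.net.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            key = f"{i}.{name}"
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            p = getattr(layer, name)
            setattr(
                layer,
                name,
                (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32),
            )
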