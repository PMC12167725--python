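"""Minimal 3D neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays in channels-last layout
``(N, D, H, W, C)``: convolutions then lower to shift-and-accumulate BLAS
matrix products over small cache-resident blocks, which is what makes CPU
training tractable. Each layer caches
what its backward pass needs during forward; gradients accumulate into
``layer.grads`` and input gradients are returned, so a model is a graph of
layer calls run in reverse.

The input gradient of a stride-1 same convolution is the full correlation
of the output gradient with the spatially flipped, channel-transposed
kernel; this and every other backward rule here is pinned by a finite-
difference gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import sgemm

__all__ = ["Conv3d", "InstanceNorm3d", "ReLU", "MaxPool2", "ConvTranspose2"]


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def param_items(self):
        return [(self.params, self.grads, k) for k in self.params]


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x


def _corr3(xp: np.ndarray, wk: np.ndarray, d: int, h: int, w: int) -> np.ndarray:
    """Valid correlation of a padded batch (N, D+2p, H+2p, W+2p, Cin) with
    (k, k, k, Cin, Cout), by shift-and-accumulate matrix products.

    Each (a, b) kernel plane slices a block whose rows are contiguous, so
    the per-offset copies run at memcpy speed instead of materializing a
    k^3-fold im2col matrix.
    """
    n = xp.shape[0]
    k, cout = wk.shape[0], wk.shape[-1]
    dhw = d * h * w
    y = np.zeros((n, dhw, cout), dtype=np.float32)
    for i in range(n):
        yt = y[i].T  # F-contiguous view: BLAS accumulates in place (beta=1)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    vc = np.ascontiguousarray(xp[i, a : a + d, b : b + h, c : c + w]).reshape(dhw, -1)
                    sgemm(1.0, wk[a, b, c].T, vc.T, beta=1.0, c=yt, overwrite_c=True)
    return y.reshape(n * dhw, cout)


class Conv3d(Layer):
    """Stride-1 'same' 3D convolution (cross-correlation), He-initialized.

    Weights are stored as (k, k, k, cin, cout). ``needs_input_grad=False``
    (first layer) skips the input-gradient pass.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 needs_input_grad: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        self.needs_input_grad = needs_input_grad
        std = np.sqrt(2.0 / (cin * k**3))
        self.params["W"] = rng.normal(0.0, std, size=(k, k, k, cin, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, _ = x.shape
        k = self.k
        if k == 1:
            self._x = x
            y = x.reshape(-1, self.cin) @ self.params["W"][0, 0, 0] + self.params["b"]
            return y.reshape(n, d, h, w, self.cout)
        xp = _pad_spatial(x, self.pad)
        self._xp = xp
        y = _corr3(xp, self.params["W"], d, h, w)
        y += self.params["b"]
        return y.reshape(n, d, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, _ = dy.shape
        p, k = self.pad, self.k
        if k == 1:
            xm = self._x.reshape(-1, self.cin)
            dym = dy.reshape(-1, self.cout)
            self.grads["W"][0, 0, 0] += xm.T @ dym
            self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
            dx = dym @ self.params["W"][0, 0, 0].T
            self._x = None
            return dx.reshape(n, d, h, w, self.cin)
        dym = np.ascontiguousarray(dy).reshape(n, d * h * w, self.cout)
        dw = self.grads["W"]
        for i in range(n):
            dyt = dym[i].T  # F view (cout, m)
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        vc = np.ascontiguousarray(
                            self._xp[i, a : a + d, b : b + h, c : c + w]
                        ).reshape(-1, self.cin)
                        # dW^T (cout, cin) accumulated via F-order views
                        sgemm(1.0, dyt, vc.T, trans_b=True, beta=1.0,
                              c=dw[a, b, c].T, overwrite_c=True)
        self._xp = None
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        if not self.needs_input_grad:
            return None
        # dx: full correlation of dy with flipped kernel, cin/cout swapped
        wback = np.ascontiguousarray(
            self.params["W"][::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        )
        dyp = _pad_spatial(dy, p)
        dx = _corr3(dyp, wback, d, h, w)
        return dx.reshape(n, d, h, w, self.cin)


class InstanceNorm3d(Layer):
    """Per-(sample, channel) normalization over the spatial axes, with affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        m = d * h * w
        s1 = np.einsum("ndhwc->nc", x, optimize=True)
        s2 = np.einsum("ndhwc,ndhwc->nc", x, x, optimize=True)
        mu = s1 / m
        var = np.maximum(s2 / m - mu * mu, 0.0)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._inv = inv[:, None, None, None, :]
        self._xhat = (x - mu[:, None, None, None, :].astype(np.float32)) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n, d, h, w, c = dy.shape
        m = d * h * w
        self.grads["gamma"] += np.einsum("ndhwc,ndhwc->c", dy, xhat, optimize=True)
        self.grads["beta"] += np.einsum("ndhwc->c", dy, optimize=True)
        dxhat = dy * self.params["gamma"]
        m1 = np.einsum("ndhwc->nc", dxhat, optimize=True)[:, None, None, None, :] / m
        m2 = (
            np.einsum("ndhwc,ndhwc->nc", dxhat, xhat, optimize=True)[:, None, None, None, :] / m
        )
        dx = inv * (dxhat - m1.astype(np.float32) - xhat * m2.astype(np.float32))
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0.0).astype(np.float32)
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2x2 max pooling with stride 2 (even spatial sizes required)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        r = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, d // 2, h // 2, w // 2, c, 8)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        out = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        out = out.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        out = out.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, d, h, w, c)
        self._idx = None
        return out


class ConvTranspose2(Layer):
    """2x2x2 transposed convolution with stride 2 (exact 2x upsampling).

    Weights are stored as (cin, 2, 2, 2, cout).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.params["W"] = rng.normal(0.0, std, size=(cin, 2, 2, 2, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, d, h, w, _ = x.shape
        wm = self.params["W"].reshape(self.cin, -1)  # (cin, 8*cout)
        t = (x.reshape(-1, self.cin) @ wm).reshape(n, d, h, w, 2, 2, 2, self.cout)
        t = t.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(n, 2 * d, 2 * h, 2 * w, self.cout)
        return (t + self.params["b"]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d2, h2, w2, _ = dy.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        dt = dy.reshape(n, d, 2, h, 2, w, 2, self.cout).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        dtm = np.ascontiguousarray(dt).reshape(-1, 8 * self.cout)  # rows match x rows
        xm = self._x.reshape(-1, self.cin)
        self.grads["W"] += (xm.T @ dtm).reshape(self.cin, 2, 2, 2, self.cout)
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        wm = self.params["W"].reshape(self.cin, -1)
        dx = (dtm @ wm.T).reshape(n, d, h, w, self.cin)
        self._x = None
        return np.ascontiguousarray(dx, dtype=np.float32)
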