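"""Minimal CNN building blocks on numpy with explicit backprop.

Data layout is channels-last, (batch, height, width, channels), float32.
3x3 convolutions use the shift-and-GEMM trick: the padded input is
multiplied once per kernel offset and accumulated with a strided add,
which keeps all heavy lifting inside BLAS.  Every layer caches what its
backward pass needs; gradients are accumulated into ``grads`` and applied
by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv3x3", "Conv1x1", "ReLU", "MaxPool2", "ConvT2x2",
           "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    np.negative(np.abs(z), out=out)
    np.exp(out, out=out)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    neg = ~pos
    out[neg] = out[neg] / (1.0 + out[neg])
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` vs targets ``y`` in {0,1}.

    Returns (loss, dloss/dz).  Numerically stable for large |z|.
    """
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / np.float32(z.size)
    return float(loss.mean()), np.asarray(dz, dtype=np.float32)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3x3(Layer):
    """3x3 same-padding convolution, weights (9, cin, cout).

    Shift-and-GEMM evaluation: the padded input is multiplied once per
    kernel offset and accumulated with a strided add, keeping the heavy
    lifting in BLAS without materializing an im2col buffer.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.params["w"] = _he_init(rng, 9 * cin, (9, cin, cout))
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def forward(self, x, train=True):
        b, h, w, cin = x.shape
        xp = np.zeros((b, h + 2, w + 2, cin), dtype=np.float32)
        xp[:, 1:h + 1, 1:w + 1, :] = x
        if train:
            self._xp = xp
        flat = xp.reshape(-1, cin)
        out = np.zeros((b, h, w, self.cout), dtype=np.float32)
        out += self.params["b"]
        wk = self.params["w"]
        pbuf = np.empty((flat.shape[0], self.cout), dtype=np.float32)
        for k in range(9):
            dy, dx = divmod(k, 3)
            np.matmul(flat, wk[k], out=pbuf)
            out += pbuf.reshape(b, h + 2, w + 2, self.cout)[:, dy:dy + h,
                                                            dx:dx + w, :]
        return out

    def backward(self, dyy):
        b, h, w, _ = dyy.shape
        xp = self._xp
        self._xp = None
        dflat = np.ascontiguousarray(dyy).reshape(-1, self.cout)
        wk = self.params["w"]
        dw = np.empty_like(wk)
        dxp = np.zeros_like(xp)
        xbuf = np.empty((b * h * w, self.cin), dtype=np.float32)
        dbuf = np.empty((b * h * w, self.cin), dtype=np.float32)
        for k in range(9):
            dy, dx = divmod(k, 3)
            np.copyto(xbuf.reshape(b, h, w, self.cin),
                      xp[:, dy:dy + h, dx:dx + w, :])
            np.matmul(xbuf.T, dflat, out=dw[k])
            np.matmul(dflat, wk[k].T, out=dbuf)
            dxp[:, dy:dy + h, dx:dx + w, :] += dbuf.reshape(b, h, w, self.cin)
        self.grads["w"] = self.grads.get("w", 0) + dw
        self.grads["b"] = self.grads.get("b", 0) + dyy.sum(axis=(0, 1, 2))
        return dxp[:, 1:h + 1, 1:w + 1, :]


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.params["w"] = _he_init(rng, cin, (cin, cout))
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._x = None

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        self._x = None
        self.grads["w"] = self.grads.get("w", 0) \
            + x.reshape(-1, self.cin).T @ dy.reshape(-1, self.cout)
        self.grads["b"] = self.grads.get("b", 0) + dy.sum(axis=(0, 1, 2))
        return dy @ self.params["w"].T


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self):
        super().__init__()
        self._idx = None
        self._shape = None

    def forward(self, x, train=True):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c) \
              .transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        b, h, w, c = self._shape
        dxr = np.zeros((b, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        self._idx = None
        self._shape = None
        return dxr.reshape(b, h // 2, w // 2, 2, 2, c) \
                  .transpose(0, 1, 3, 2, 4, 5).reshape(b, h, w, c)


class ConvT2x2(Layer):
    """2x2 transposed convolution, stride 2 (doubles height and width)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.params["w"] = _he_init(rng, cin, (cin, 4 * cout))
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self._x = None

    def forward(self, x, train=True):
        b, h, w, cin = x.shape
        if train:
            self._x = x
        p = (x.reshape(-1, cin) @ self.params["w"]) \
            .reshape(b, h, w, 2, 2, self.cout)
        out = p.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, self.cout)
        return out + self.params["b"]

    def backward(self, dy):
        x = self._x
        self._x = None
        b, h2, w2, cout = dy.shape
        h, w = h2 // 2, w2 // 2
        dp = dy.reshape(b, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5) \
               .reshape(-1, 4 * cout)
        self.grads["w"] = self.grads.get("w", 0) \
            + x.reshape(-1, self.cin).T @ dp
        self.grads["b"] = self.grads.get("b", 0) + dy.sum(axis=(0, 1, 2))
        return (dp @ self.params["w"].T).reshape(b, h, w, self.cin)


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            layer.grads.clear()
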