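"""Minimal CPU layer stack with hand-derived backprop.

Implements exactly the pieces a fully-convolutional segmentation network
needs — convolution, batch norm, ReLU, max pooling, bilinear upsampling,
residual addition — on float32 numpy arrays in NCHW layout, each layer with
an explicit ``backward``.  Deliberately small and dependency-free so that
training runs and is reproducible anywhere numpy runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "UpsampleBilinear",
    "Sequential",
    "Bottleneck",
    "SGD",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        """List of {'value': array, 'grad': array, 'decay': bool} slots."""
        return []


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col matmul."""

    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.w = rng.normal(0, std, size=(cout, cin * k * k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = _pad(x, p)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        y = cols @ self.w.T
        if self.b is not None:
            y += self.b
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, grad):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = grad.shape[2], grad.shape[3]
        g = grad.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.cout)
        self.dw += np.tensordot(g, cols, axes=([0, 1], [0, 1]))
        if self.b is not None:
            self.db += g.sum(axis=(0, 1))
        dcols = (g @ self.w).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[..., i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self):
        out = [{"value": self.w, "grad": self.dw, "decay": True}]
        if self.b is not None:
            out.append({"value": self.b, "grad": self.db, "decay": False})
        return out


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gxsum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] * (g - gsum / m - xhat * gxsum / m)

    def parameters(self):
        return [
            {"value": self.gamma, "grad": self.dgamma, "decay": False},
            {"value": self.beta, "grad": self.dbeta, "decay": False},
        ]


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k=2, stride=None, pad=0):
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=4)
        if train:
            self._cache = (idx, x.shape, xp.shape)
        return flat.max(axis=4)

    def backward(self, grad):
        idx, xshape, xpshape = self._cache
        k, s, p = self.k, self.stride, self.pad
        n, c, ho, wo = grad.shape
        dxp = np.zeros((n, c) + xpshape[2:], dtype=np.float32)
        ns, cs, hs, ws = np.ix_(np.arange(n), np.arange(c), np.arange(ho), np.arange(wo))
        rows = hs * s + idx // k
        cols = ws * s + idx % k
        np.add.at(dxp, (ns, cs, rows, cols), grad)
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]]


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense interpolation matrix, half-pixel-centre convention."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = np.clip((o + 0.5) * scale - 0.5, 0, n_in - 1)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        a[o, i0] += 1 - t
        a[o, i1] += t
    return a


class UpsampleBilinear(Layer):
    """Bilinear upsampling by an integer factor (separable matrix form)."""

    def __init__(self, factor: int):
        self.factor = factor
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    def _mat(self, n_in):
        key = (n_in, n_in * self.factor)
        if key not in self._mats:
            self._mats[key] = _bilinear_matrix(key[1], n_in)
        return self._mats[key]

    def forward(self, x, train=True):
        ar, ac = self._mat(x.shape[2]), self._mat(x.shape[3])
        if train:
            self._cache = (ar, ac)
        return np.matmul(np.matmul(ar, x), ac.T)

    def backward(self, grad):
        ar, ac = self._cache
        return np.matmul(np.matmul(ar.T, grad), ac)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Bottleneck(Layer):
    """ResNet bottleneck: 1×1 → 3×3 (stride) → 1×1 with projected shortcut."""

    def __init__(self, cin, mid, stride, rng):
        cout = mid * 4
        self.main = Sequential(
            Conv2d(cin, mid, 1, bias=False, rng=rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, mid, 3, stride=stride, bias=False, rng=rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout),
        )
        self.project = None
        if stride != 1 or cin != cout:
            self.project = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, bias=False, rng=rng),
                BatchNorm2d(cout),
            )
        self.relu = ReLU()

    def forward(self, x, train=True):
        main = self.main.forward(x, train)
        short = self.project.forward(x, train) if self.project else x
        return self.relu.forward(main + short, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        gx = self.main.backward(grad)
        gx = gx + (self.project.backward(grad) if self.project else grad)
        return gx

    def parameters(self):
        out = self.main.parameters()
        if self.project:
            out += self.project.parameters()
        return out


class Optimizer:
    def __init__(self, params, max_grad_norm=None):
        self.params = params
        self.max_grad_norm = max_grad_norm

    def zero_grad(self):
        for p in self.params:
            p["grad"][...] = 0.0

    def _clip(self):
        """Scale all gradients so their global L2 norm stays bounded."""
        if self.max_grad_norm is None:
            return
        total = np.sqrt(sum(float((p["grad"] ** 2).sum()) for p in self.params))
        if total > self.max_grad_norm:
            scale = self.max_grad_norm / (total + 1e-12)
            for p in self.params:
                p["grad"] *= scale


class SGD(Optimizer):
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0, max_grad_norm=None):
        super().__init__(params, max_grad_norm)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p["value"]) for p in params]

    def step(self):
        self._clip()
        for p, v in zip(self.params, self._vel):
            g = p["grad"]
            if self.weight_decay and p["decay"]:
                g = g + self.weight_decay * p["value"]
            v *= self.momentum
            v -= self.lr * g
            p["value"] += v


class Adam(Optimizer):
    """Adam with the usual bias correction; weight decay added to the gradient."""

    def __init__(
        self,
        params,
        lr,
        betas=(0.9, 0.999),
        eps=1e-8,
        weight_decay=0.0,
        max_grad_norm=None,
    ):
        super().__init__(params, max_grad_norm)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p["value"]) for p in params]
        self._v = [np.zeros_like(p["value"]) for p in params]
        self._t = 0

    def step(self):
        self._clip()
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            g = p["grad"]
            if self.weight_decay and p["decay"]:
                g = g + self.weight_decay * p["value"]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
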