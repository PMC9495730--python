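"""Minimal trainable convolutional network in NumPy.

A compact residual network ("small_resnet") sized for CPU training on small
texture patches: im2col 3x3 convolutions, batch normalization, ReLU,
identity residual blocks, 2x2 average pooling, global average pooling and a
dense softmax head. Forward, backward and the Adam / SGD-with-momentum /
RMSprop update rules are implemented here; everything is deterministic given
a seed.

Layout is NHWC throughout. Parameters are plain float64 ndarrays so that
checkpoints round-trip exactly through ``numpy.savez``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallResNet", "Optimizer", "softmax", "cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / probs.shape[0])


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x padded NHWC -> (N*Ho*Wo, k*k*C), Ho=H-k+1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # win: (N, Ho, Wo, C, k, k) -> (N, Ho, Wo, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n * ho * wo, -1)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    # inverse of _im2col: scatter-add columns back onto the padded image
    n, h, w, c = shape
    ho, wo = h - k + 1, w - k + 1
    x = np.zeros(shape)
    cols = cols.reshape(n, ho, wo, k, k, c)
    for i in range(k):
        for j in range(k):
            x[:, i : i + ho, j : j + wo, :] += cols[:, :, :, i, j, :]
    return x


class _Conv3x3:
    """Same-padded 3x3 convolution (no bias; batch norm follows)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = 9 * cin
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(9 * cin, cout))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _im2col(xp, 3)
        out = (cols @ self.w).reshape(n, h, w, -1)
        if train:
            self._cache = (cols, xp.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape = self._cache
        cout = dy.shape[-1]
        dyf = dy.reshape(-1, cout)
        self.dw = cols.T @ dyf
        dcols = dyf @ self.w.T
        dxp = _col2im(dcols, xp_shape, 3)
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("w", "dw")]


class _BatchNorm:
    """Per-channel batch normalization over (N, H, W).

    Training batches use batch statistics and update exponential running
    moments; inference uses the running moments, so prediction is a pure
    function of the saved parameters. The momentum is high (0.3) because
    desk-scale epochs are only a handful of mini-batches: running moments
    must track the batch moments within one epoch or early validation
    accuracy misreports the network's state.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.3):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._istd
            self._m = x.shape[0] * x.shape[1] * x.shape[2]
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 1, 2)
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        m = self._m
        dx = (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) * self._istd
        return dx

    def params(self):
        return [("gamma", "dgamma"), ("beta", "dbeta")]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class _AvgPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        self._in_shape = x.shape
        xt = x[:, : 2 * ho, : 2 * wo, :].reshape(n, ho, 2, wo, 2, c)
        return xt.mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * ho, : 2 * wo, :] = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        return dx

    def params(self):
        return []


class _ConvBNReLU:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = _Conv3x3(cin, cout, rng)
        self.bn = _BatchNorm(cout)
        self.relu = _ReLU()

    def forward(self, x, train):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class _Residual:
    """y = relu(x + bn(conv(relu(bn(conv(x)))))) with matching channels."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.c1 = _Conv3x3(channels, channels, rng)
        self.b1 = _BatchNorm(channels)
        self.r1 = _ReLU()
        self.c2 = _Conv3x3(channels, channels, rng)
        self.b2 = _BatchNorm(channels)
        self.rout = _ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.b1.forward(self.c1.forward(x, train), train)
        y = self.r1.forward(y, train)
        y = self.b2.forward(self.c2.forward(y, train), train)
        return self.rout.forward(x + y, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.rout.backward(dy)
        dbranch = self.c1.backward(self.b1.backward(self.r1.backward(self.c2.backward(self.b2.backward(d)))))
        return d + dbranch


class SmallResNet:
    """Small residual classifier: stem conv, two residual stages, dense head.

    Input is (N, size, size, 3) floats in [0, 1]; output is (N, n_classes)
    logits. About 20k parameters at the default width — enough for
    color/texture separation, trainable on one CPU in seconds per epoch at
    desk-scale patch counts.
    """

    def __init__(self, input_size: int, n_classes: int, seed: int, width: int = 12):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.n_classes = n_classes
        self.width = width
        self.stem = _ConvBNReLU(3, width, rng)
        self.block1 = _Residual(width, rng)
        self.pool1 = _AvgPool2()
        self.widen = _ConvBNReLU(width, 2 * width, rng)
        self.block2 = _Residual(2 * width, rng)
        self.pool2 = _AvgPool2()
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / (2 * width)), size=(2 * width, n_classes))
        self.head_b = np.zeros(n_classes)

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.stem.forward(x - 0.5, train)
        h = self.pool1.forward(self.block1.forward(h, train), train)
        h = self.widen.forward(h, train)
        h = self.pool2.forward(self.block2.forward(h, train), train)
        self._gap_shape = h.shape
        feat = h.mean(axis=(1, 2))
        if train:
            self._feat = feat
        return feat @ self.head_w + self.head_b

    def backward(self, dlogits: np.ndarray) -> None:
        self.dhead_w = self._feat.T @ dlogits
        self.dhead_b = dlogits.sum(axis=0)
        dfeat = dlogits @ self.head_w.T
        n, hh, ww, c = self._gap_shape
        dh = np.broadcast_to(dfeat[:, None, None, :], self._gap_shape) / (hh * ww)
        dh = self.block2.backward(self.pool2.backward(dh))
        dh = self.widen.backward(dh)
        dh = self.block1.backward(self.pool1.backward(dh))
        self.stem.backward(dh)

    # ---- parameter access ---------------------------------------------------

    def _units(self):
        units = []
        for cb in (self.stem, self.widen):
            units += [cb.conv, cb.bn]
        for block in (self.block1, self.block2):
            units += [block.c1, block.b1, block.c2, block.b2]
        return units

    def parameters(self) -> list[np.ndarray]:
        out = []
        for u in self._units():
            for pname, _ in u.params():
                out.append(getattr(u, pname))
        out += [self.head_w, self.head_b]
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for u in self._units():
            for _, gname in u.params():
                out.append(getattr(u, gname))
        out += [self.dhead_w, self.dhead_b]
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All persisted arrays: parameters plus batch-norm running moments."""
        out = self.parameters()
        for u in self._units():
            if isinstance(u, _BatchNorm):
                out += [u.running_mean, u.running_var]
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        expected = len(self.state_arrays())
        if len(arrays) != expected:
            raise ValueError(f"expected {expected} state arrays, got {len(arrays)}")
        arrays = [np.array(a, dtype=np.float64) for a in arrays]
        i = 0
        for u in self._units():
            for pname, _ in u.params():
                setattr(u, pname, arrays[i])
                i += 1
        self.head_w = arrays[i]
        self.head_b = arrays[i + 1]
        i += 2
        for u in self._units():
            if isinstance(u, _BatchNorm):
                u.running_mean = arrays[i]
                u.running_var = arrays[i + 1]
                i += 2

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.n_classes))


class Optimizer:
    """Adam / SGD-with-momentum / RMSprop over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], kind: str = "adam", lr: float = 1e-3):
        self.params = params
        self.kind = kind
        self.lr = lr
        self.t = 0
        if kind == "adam":
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        elif kind == "sgdm":
            self.m = [np.zeros_like(p) for p in params]
        elif kind == "rmsprop":
            self.v = [np.zeros_like(p) for p in params]
        else:
            raise ValueError(f"unknown optimizer: {kind!r}")

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        if self.kind == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            for p, g, m, v in zip(self.params, grads, self.m, self.v):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        elif self.kind == "sgdm":
            for p, g, m in zip(self.params, grads, self.m):
                m *= 0.9
                m += g
                p -= self.lr * m
        else:  # rmsprop
            for p, g, v in zip(self.params, grads, self.v):
                v *= 0.9
                v += 0.1 * g * g
                p -= self.lr * g / (np.sqrt(v) + 1e-8)
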