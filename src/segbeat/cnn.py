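"""A compact numpy implementation of 1-D convolutional networks.

Provides exactly the layers the rhythm-segment classifier needs: same-padded
1-D convolution, max pooling, inverted dropout, dense layers, batch
normalization, ReLU, and a sigmoid/binary-cross-entropy head trained with
Adam.  Tensors are ``(batch, length, channels)``; all randomness flows
through one seeded Generator.
"""
from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution, weights (kernel*in_ch, out_ch)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.kernel, self.in_ch, self.out_ch = kernel, in_ch, out_ch
        self.W = rng.normal(0.0, scale, (kernel * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (n, L, c, kernel) -> (n, L, kernel*c)
        return win.transpose(0, 1, 3, 2).reshape(n, L, self.kernel * c)

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, g):
        n, L, _ = g.shape
        cols2 = self._cols.reshape(n * L, -1)
        g2 = g.reshape(n * L, self.out_ch)
        self.dW[...] = cols2.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, L, self.kernel, self.in_ch)
        p = self.kernel // 2
        dxp = np.zeros((n, L + 2 * p, self.in_ch))
        for k in range(self.kernel):
            dxp[:, k : k + L] += dcols[:, :, k]
        return dxp[:, p : p + L]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        n, L, c = x.shape
        Lc = (L // self.pool) * self.pool
        self._L = L
        xr = x[:, :Lc].reshape(n, Lc // self.pool, self.pool, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, g):
        n, Lp, c = g.shape
        dx = np.zeros((n, self._L, c))
        dxr = np.zeros((n, Lp, self.pool, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx[:, : Lp * self.pool] = dxr.reshape(n, Lp * self.pool, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ReLU(Layer):
    def forward(self, x, train):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (batch, features)."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.run_mean = np.zeros(dim)
        self.run_var = np.ones(dim)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        n = g.shape[0]
        self.dgamma[...] = (g * self._xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        gx = g * self.gamma
        return (gx - gx.mean(axis=0)
                - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
            if isinstance(layer, BatchNorm):
                out.extend([layer.run_mean, layer.run_var])
        return out

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.run_mean[...] = next(it)
                layer.run_var[...] = next(it)


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.net.parameters()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    grad = (p - targets) / targets.size
    return loss, grad
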