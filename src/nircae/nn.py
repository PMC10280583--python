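"""Minimal NumPy building blocks for 1-D convolutional networks.

Layers operate on float64 arrays of shape ``(batch, length, channels)``
(sequence layers) or ``(batch, features)`` (dense layers). Each layer
implements ``forward`` (caching what backward needs) and ``backward``
(returning the gradient w.r.t. its input and filling ``grads`` for its
parameters), so a network is just an ordered layer list and reverse-mode
differentiation is a reversed loop. Gradient correctness is validated
against central finite differences in the test suite rather than assumed.

Conventions:

* convolutions are cross-correlations with stride 1 and zero-padded
  "same" output length (odd kernels);
* max pooling is non-overlapping (stride = pool size);
* upsampling repeats each element ``factor`` times (nearest neighbour);
* activations: ``tanh`` or ``linear``, applied inside the layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameterless, shape-preserving by default."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


class _Activated(Layer):
    def __init__(self, activation: str):
        super().__init__()
        if activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def _act(self, z):
        if self.activation == "tanh":
            a = np.tanh(z)
            self._act_cache = a
            return a
        return z

    def _act_grad(self, grad):
        if self.activation == "tanh":
            return grad * (1.0 - self._act_cache ** 2)
        return grad


class Conv1D(_Activated):
    """Same-padded 1-D convolution, stride 1, odd kernel.

    Weight shape ``(kernel, in_channels, out_channels)``; one bias per
    output channel, so the trainable-parameter count is
    ``kernel * in_channels * out_channels + out_channels``.

    A transposed convolution with stride 1 and same padding is the same
    linear map with a flipped kernel, so the decoder's transposed
    convolutions reuse this layer (identical parameter counts).
    """

    def __init__(self, in_channels, out_channels, kernel_size,
                 activation="tanh", *, rng=None, name="conv"):
        super().__init__(activation)
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.name = name
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * out_channels
        w = _glorot_uniform(rng, (kernel_size, in_channels, out_channels),
                            fan_in, fan_out)
        b = np.zeros(out_channels)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    @property
    def pad(self):
        return self.kernel_size // 2

    def forward(self, x):
        w, b = self.params
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        win = sliding_window_view(xp, self.kernel_size, axis=1)  # (n,L,C,k)
        self._win = win
        z = np.einsum("nlck,kco->nlo", win, w, optimize=True) + b
        return self._act(z)

    def backward(self, grad):
        grad = self._act_grad(grad)
        w, _ = self.params
        self.grads[0][...] = np.einsum(
            "nlck,nlo->kco", self._win, grad, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        gp = np.pad(grad, ((0, 0), (self.pad, self.pad), (0, 0)))
        gwin = sliding_window_view(gp, self.kernel_size, axis=1)  # (n,L,O,k)
        return np.einsum("nlok,kco->nlc", gwin, w[::-1], optimize=True)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis."""

    def __init__(self, pool_size=2, name="pool"):
        super().__init__()
        self.pool_size = pool_size
        self.name = name

    def forward(self, x):
        n, L, c = x.shape
        p = self.pool_size
        if L % p:
            raise ValueError(f"length {L} not divisible by pool size {p}")
        r = x.reshape(n, L // p, p, c)
        self._idx = r.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, Lp, c = grad.shape
        dx = np.zeros((n, Lp, self.pool_size, c))
        np.put_along_axis(dx, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return dx.reshape(self._in_shape)


class Upsample1D(Layer):
    """Nearest-neighbour repetition along the sequence axis."""

    def __init__(self, factor=2, name="upsample"):
        super().__init__()
        self.factor = factor
        self.name = name

    def forward(self, x):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad):
        n, L, c = grad.shape
        return grad.reshape(n, L // self.factor, self.factor, c).sum(axis=2)


class Flatten(Layer):
    def __init__(self, name="flatten"):
        super().__init__()
        self.name = name

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape, name="reshape"):
        super().__init__()
        self.shape = tuple(shape)
        self.name = name

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Dense(_Activated):
    """Fully connected layer; parameters = in*out weights + out biases."""

    def __init__(self, in_features, out_features, activation="tanh",
                 *, rng=None, name="dense"):
        super().__init__(activation)
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        rng = rng or np.random.default_rng()
        w = _glorot_uniform(rng, (in_features, out_features),
                            in_features, out_features)
        b = np.zeros(out_features)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x):
        self._x = x
        w, b = self.params
        return self._act(x @ w + b)

    def backward(self, grad):
        grad = self._act_grad(grad)
        w, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ w.T


def forward_layers(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def mse_loss_and_grad(pred, target):
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    resid = pred - target
    loss = float(np.mean(resid ** 2))
    return loss, 2.0 * resid / resid.size


def reconstruction_loss_and_grads(layers, x):
    """Autoencoder pass: forward all layers, MSE against the input, backward.

    Returns the loss; per-parameter gradients are left in each layer's
    ``grads`` (used directly by the optimizer and by the finite-difference
    checks in the tests).
    """
    pred = forward_layers(layers, x)
    loss, grad = mse_loss_and_grad(pred, x)
    for layer in reversed(layers):
        grad = layer.backward(grad)
    return loss


class Adam:
    """Adam optimizer with bias correction (shared step counter)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class EarlyStopping:
    """Stop when the monitored loss rises on `patience` consecutive epochs.

    Tracks the best (lowest) loss seen so the caller can restore the
    weights from that epoch. ``update`` returns True when training should
    stop.
    """

    def __init__(self, patience: int = 2):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self._prev = np.inf
        self._rises = 0
        self.stopped = False

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
        if loss > self._prev:
            self._rises += 1
        else:
            self._rises = 0
        self._prev = loss
        if self._rises >= self.patience:
            self.stopped = True
        return self.stopped
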