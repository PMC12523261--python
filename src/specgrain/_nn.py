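"""NumPy feed-forward and 1-D convolutional regression networks.

Small, fully deterministic (seeded) implementations with manual
backpropagation and an Adam optimizer. The convolutional network exposes its
second convolutional layer's activations and the gradient of the scalar
output with respect to them, which is exactly what Grad-CAM++ consumes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, FitError

__all__ = ["Adam", "MLPRegressorNet", "ConvNet1D", "train_net",
           "min_input_length"]


def min_input_length(kernels, pool: int = 2) -> int:
    """Smallest input length the conv1-pool-conv2-pool stack accepts."""
    k1, k2 = kernels
    n = k1 + 1
    while True:
        L1 = n - k1 + 1
        P1 = L1 // pool
        L2 = P1 - k2 + 1
        if L1 >= 2 and L2 >= 2 and L2 // pool >= 1:
            return n
        n += 1


class Adam:
    """Adam updates over a flat list of parameter arrays (in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _relu(x):
    return np.maximum(x, 0.0)


class MLPRegressorNet:
    """One-hidden-layer ReLU network with a scalar output (BPNN).

    Glorot-uniform initialization: for a shallow network it generalizes
    markedly better than He scaling, which overweights the first layer and
    encourages memorization on small calibration sets.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        b1 = np.sqrt(6.0 / (n_in + hidden))
        b2 = np.sqrt(6.0 / (hidden + 1))
        self.W1 = rng.uniform(-b1, b1, (n_in, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.uniform(-b2, b2, (hidden, 1))
        self.b2 = np.zeros(1)
        self._cache = None

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X, cache=False):
        z1 = X @ self.W1 + self.b1
        h = _relu(z1)
        out = (h @ self.W2 + self.b2).ravel()
        if cache:
            self._cache = (X, z1, h)
        return out

    def backward(self, dout):
        X, z1, h = self._cache
        dout = dout[:, None]
        dW2 = h.T @ dout
        db2 = dout.sum(axis=0)
        dh = dout @ self.W2.T
        dz1 = dh * (z1 > 0)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dW2, db2]


def _conv1d(x, W, b):
    # x: (B, Cin, L), W: (Cout, Cin, k) -> (B, Cout, L-k+1)
    win = sliding_window_view(x, W.shape[2], axis=2)
    return np.einsum("bilk,oik->bol", win, W, optimize=True) + b[None, :, None]


def _conv1d_backward(x, W, dz):
    win = sliding_window_view(x, W.shape[2], axis=2)
    dW = np.einsum("bol,bilk->oik", dz, win, optimize=True)
    db = dz.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    L_out = dz.shape[2]
    for j in range(W.shape[2]):
        dx[:, :, j:j + L_out] += np.einsum("bol,oi->bil", dz, W[:, :, j],
                                           optimize=True)
    return dx, dW, db


def _maxpool2(x):
    B, C, L = x.shape
    L2 = L // 2
    xr = x[:, :, :2 * L2].reshape(B, C, L2, 2)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx, L


def _unpool2(d, idx, L):
    B, C, L2 = d.shape
    dr = np.zeros((B, C, L2, 2))
    np.put_along_axis(dr, idx[..., None], d[..., None], axis=3)
    out = np.zeros((B, C, L))
    out[:, :, :2 * L2] = dr.reshape(B, C, 2 * L2)
    return out


class ConvNet1D:
    """conv(16,k7)-pool2-conv(32,k5)-pool2 + fc 256-64-1, all ReLU.

    Five trainable layers: two 1-D convolutions and three fully connected
    layers. ``conv_activation``/``forward_from`` give named access to the
    post-ReLU feature maps for saliency analysis.
    """

    def __init__(self, n_in: int, rng: np.random.Generator,
                 channels=(16, 32), kernels=(7, 5), fc_sizes=(256, 64)):
        c1, c2 = channels
        k1, k2 = kernels
        L1 = n_in - k1 + 1
        P1 = L1 // 2
        L2 = P1 - k2 + 1
        P2 = L2 // 2
        if L1 < 2 or L2 < 2 or P2 < 1:
            raise ConfigError(
                f"input length {n_in} is below the receptive field of the "
                f"conv stack (kernels {kernels}, pool 2)"
            )
        self.n_in = n_in
        self.shapes = {"conv1": L1, "pool1": P1, "conv2": L2, "pool2": P2}
        self.Wc1 = rng.normal(0.0, np.sqrt(2.0 / k1), (c1, 1, k1))
        self.bc1 = np.zeros(c1)
        self.Wc2 = rng.normal(0.0, np.sqrt(2.0 / (c1 * k2)), (c2, c1, k2))
        self.bc2 = np.zeros(c2)
        flat = c2 * P2
        f1, f2 = fc_sizes
        self.Wf1 = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, f1))
        self.bf1 = np.zeros(f1)
        self.Wf2 = rng.normal(0.0, np.sqrt(2.0 / f1), (f1, f2))
        self.bf2 = np.zeros(f2)
        self.Wf3 = rng.normal(0.0, np.sqrt(2.0 / f2), (f2, 1))
        self.bf3 = np.zeros(1)
        self._cache = None

    @property
    def layer_names(self):
        return ("conv1", "conv2")

    @property
    def params(self):
        return [self.Wc1, self.bc1, self.Wc2, self.bc2,
                self.Wf1, self.bf1, self.Wf2, self.bf2, self.Wf3, self.bf3]

    def forward(self, X, cache=False):
        x0 = np.asarray(X, dtype=float)[:, None, :]
        z1 = _conv1d(x0, self.Wc1, self.bc1)
        a1 = _relu(z1)
        p1, i1, L1 = _maxpool2(a1)
        z2 = _conv1d(p1, self.Wc2, self.bc2)
        a2 = _relu(z2)
        p2, i2, L2 = _maxpool2(a2)
        f = p2.reshape(p2.shape[0], -1)
        zf1 = f @ self.Wf1 + self.bf1
        h1 = _relu(zf1)
        zf2 = h1 @ self.Wf2 + self.bf2
        h2 = _relu(zf2)
        out = (h2 @ self.Wf3 + self.bf3).ravel()
        if cache:
            self._cache = (x0, z1, p1, i1, L1, z2, a2, p2, i2, L2,
                           f, zf1, h1, zf2, h2)
        return out

    def backward(self, dout):
        (x0, z1, p1, i1, L1, z2, a2, p2, i2, L2,
         f, zf1, h1, zf2, h2) = self._cache
        dout = dout[:, None]
        dWf3 = h2.T @ dout
        dbf3 = dout.sum(axis=0)
        dh2 = dout @ self.Wf3.T
        dzf2 = dh2 * (zf2 > 0)
        dWf2 = h1.T @ dzf2
        dbf2 = dzf2.sum(axis=0)
        dh1 = dzf2 @ self.Wf2.T
        dzf1 = dh1 * (zf1 > 0)
        dWf1 = f.T @ dzf1
        dbf1 = dzf1.sum(axis=0)
        df = dzf1 @ self.Wf1.T
        dp2 = df.reshape(p2.shape)
        da2 = _unpool2(dp2, i2, L2)
        dz2 = da2 * (z2 > 0)
        dp1, dWc2, dbc2 = _conv1d_backward(p1, self.Wc2, dz2)
        da1 = _unpool2(dp1, i1, L1)
        dz1 = da1 * (z1 > 0)
        _, dWc1, dbc1 = _conv1d_backward(x0, self.Wc1, dz1)
        return [dWc1, dbc1, dWc2, dbc2, dWf1, dbf1, dWf2, dbf2, dWf3, dbf3]

    # -- named-layer access for saliency ------------------------------------

    def conv_activation(self, X, layer: str):
        """Post-ReLU feature maps of a named conv layer, shape (B, C, L)."""
        self._check_layer(layer)
        x0 = np.asarray(X, dtype=float)[:, None, :]
        a1 = _relu(_conv1d(x0, self.Wc1, self.bc1))
        if layer == "conv1":
            return a1
        p1, _, _ = _maxpool2(a1)
        return _relu(_conv1d(p1, self.Wc2, self.bc2))

    def forward_from(self, A, layer: str):
        """Run the network head on given feature maps of ``layer``."""
        self._check_layer(layer)
        A = np.asarray(A, dtype=float)
        if layer == "conv1":
            p1, _, _ = _maxpool2(A)
            A = _relu(_conv1d(p1, self.Wc2, self.bc2))
        p2, _, _ = _maxpool2(A)
        f = p2.reshape(p2.shape[0], -1)
        h1 = _relu(f @ self.Wf1 + self.bf1)
        h2 = _relu(h1 @ self.Wf2 + self.bf2)
        return (h2 @ self.Wf3 + self.bf3).ravel()

    def activation_and_gradient(self, X, layer: str = "conv2"):
        """Feature maps A of ``layer`` and per-sample dY/dA, both (B, C, L).

        Y is the scalar regression output; samples are independent, so a
        batched backward pass with unit output gradient yields each sample's
        own gradient.
        """
        self._check_layer(layer)
        out = self.forward(X, cache=True)
        (x0, z1, p1, i1, L1, z2, a2, p2, i2, L2,
         f, zf1, h1, zf2, h2) = self._cache
        ones = np.ones((len(out), 1))
        dh2 = ones @ self.Wf3.T
        dzf2 = dh2 * (zf2 > 0)
        dh1 = dzf2 @ self.Wf2.T
        dzf1 = dh1 * (zf1 > 0)
        df = dzf1 @ self.Wf1.T
        dp2 = df.reshape(p2.shape)
        dA2 = _unpool2(dp2, i2, L2)
        if layer == "conv2":
            return a2, dA2
        dz2 = dA2 * (z2 > 0)
        dp1, _, _ = _conv1d_backward(p1, self.Wc2, dz2)
        dA1 = _unpool2(dp1, i1, L1)
        return _relu(z1), dA1

    def _check_layer(self, layer: str):
        if layer not in self.layer_names:
            raise ConfigError(
                f"unknown layer {layer!r}; available layers: {list(self.layer_names)}"
            )

    def state_dict(self) -> dict:
        names = ["Wc1", "bc1", "Wc2", "bc2", "Wf1", "bf1", "Wf2", "bf2",
                 "Wf3", "bf3"]
        return {n: getattr(self, n).copy() for n in names}

    def load_state_dict(self, d: dict):
        for n, v in d.items():
            getattr(self, n)[...] = v


def train_net(net, X, y, epochs: int, batch_size: int, lr: float,
              rng: np.random.Generator):
    """Mini-batch Adam training on mean-squared-error loss.

    Returns the per-epoch training-loss curve. Raises FitError if the loss
    becomes non-finite (divergence), reporting the epoch.
    """
    n = len(y)
    opt = Adam(net.params, lr=lr)
    curve = np.empty(epochs)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, batch_size):
            b = order[s:s + batch_size]
            pred = net.forward(X[b], cache=True)
            err = pred - y[b]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FitError(f"training diverged (non-finite loss) at epoch {epoch}")
            grads = net.backward(2.0 * err / len(b))
            opt.step(net.params, grads)
            total += loss * len(b)
        curve[epoch] = total / n
    return curve
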