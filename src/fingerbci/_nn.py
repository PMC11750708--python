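"""Minimal NumPy feed-forward network machinery for the velocity decoder.

Implements exactly the pieces the decoder needs: dense layers with Kaiming
initialization, ReLU, batch normalization (standard, and a variance-only
variant that never subtracts a mean and never learns a bias), inverted
dropout, the Adam optimizer with optional L2 weight decay, and a
mean-squared-error loss.  All forward/backward passes are hand-written; no
autograd framework is used, so inference is a pure function of (params,
input) and training is deterministic given a seeded generator.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def kaiming_normal(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    """He-normal init for ReLU networks: N(0, 2/fan_in)."""
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear:
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.w = kaiming_normal(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out

    def infer(self, x: np.ndarray) -> np.ndarray:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ grad
        if self.b is not None:
            self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params_grads(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class TemporalConv:
    """Shared-weight contraction of 3 time bins to n_features per channel.

    Input (batch, n_channels, 3) -> output (batch, n_channels, n_features);
    the (3, n_features) weights are shared across channels, acting as a
    length-3 temporal convolution evaluated at the most recent bin.
    """

    def __init__(self, rng, n_bins: int, n_features: int):
        self.w = kaiming_normal(rng, n_bins, (n_bins, n_features))
        self.b = np.zeros(n_features)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    infer = forward  # stateless apart from the cached input

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # x: (B, C, T); grad: (B, C, F)
        self.gw = np.einsum("bct,bcf->tf", self._x, grad)
        self.gb = grad.sum(axis=(0, 1))
        return grad @ self.w.T

    def params_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def parameters(self):
        return [self.w, self.b]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def infer(self, x):
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask

    def params_grads(self):
        return []

    def parameters(self):
        return []


class BatchNorm:
    """Per-feature batch normalization.

    ``apply_mean=False`` gives the variance-only variant: the output is
    ``gamma * x / sqrt(var + eps)`` with no mean subtraction in either train
    or eval mode (the variance itself is still the centered batch variance).
    ``learn_bias=False`` removes the beta parameter.
    """

    def __init__(self, n_features: int, apply_mean: bool = True, learn_bias: bool = True):
        self.apply_mean = apply_mean
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features) if learn_bias else None
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
        self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xc = x - mu
        self._core = (self._xc if self.apply_mean else x) * self._inv_std
        out = self.gamma * self._core
        if self.beta is not None:
            out = out + self.beta
        return out

    def infer(self, x: np.ndarray) -> np.ndarray:
        inv_std = 1.0 / np.sqrt(self.running_var + _BN_EPS)
        core = (x - self.running_mean if self.apply_mean else x) * inv_std
        out = self.gamma * core
        if self.beta is not None:
            out = out + self.beta
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b = grad.shape[0]
        self.ggamma = (grad * self._core).sum(axis=0)
        if self.beta is not None:
            self.gbeta = grad.sum(axis=0)
        g = grad * self.gamma  # gradient w.r.t. core * inv_std pre-gamma
        if self.apply_mean:
            # standard BN backward
            dx = (
                self._inv_std
                / b
                * (b * g - g.sum(axis=0) - self._xc * self._inv_std**2 * (g * self._xc).sum(axis=0))
            )
        else:
            # y_i = x_i * s with s = (var+eps)^-1/2 and centered var:
            # dx_j = s*g_j - xc_j * s^3/b * sum_i g_i x_i
            x = self._core / self._inv_std
            dot = (g * x).sum(axis=0)
            dx = g * self._inv_std - self._xc * (self._inv_std**3 / b) * dot
        return dx

    def params_grads(self):
        out = [(self.gamma, self.ggamma)]
        if self.beta is not None:
            out.append((self.beta, self.gbeta))
        return out

    def parameters(self):
        return [self.gamma] + ([self.beta] if self.beta is not None else [])


class Dropout:
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, rng: np.random.Generator):
        if self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def infer(self, x):
        return x

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params_grads(self):
        return []

    def parameters(self):
        return []


class Adam:
    """Adam with torch-style L2 weight decay (decay added to the gradient)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss_and_grad(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / diff.size
    return loss, grad
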