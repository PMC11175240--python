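"""Minimal dense neural-network layers with hand-written backprop and Adam.

Supports exactly what the tabular GAN architectures need: dense layers,
LeakyReLU, batch normalisation, tanh / sigmoid outputs, binary cross-entropy
with logits, and an Adam optimizer.  Everything is numpy and fully
deterministic given the seeding Generator.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class LeakyReLU:
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)

    params: list = []
    grads: list = []


class BatchNorm:
    """Batch normalisation over axis 0 with running statistics for sampling."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.ggamma = (grad * self._xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        gxhat = grad * self.gamma
        return (gxhat - gxhat.mean(axis=0)
                - self._xhat * (gxhat * self._xhat).mean(axis=0)) / self._std

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.ggamma, self.gbeta]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Stable binary cross-entropy; returns (mean loss, dL/dlogits)."""
    p = sigmoid(logits)
    loss = np.mean(np.maximum(logits, 0) - logits * targets
                   + np.log1p(np.exp(-np.abs(logits))))
    grad = (p - targets) / len(logits)
    return float(loss), grad
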