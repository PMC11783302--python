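"""Minimal feed-forward building blocks with explicit backpropagation.

Layers cache what their backward pass needs; ``backward`` returns the
gradient with respect to the layer input and stores parameter gradients on
the layer.  Evaluation-mode batch normalization is an affine map using
running statistics, so input gradients at inference are exact.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init suited to downstream ReLU
        scale = np.sqrt(2.0 / n_in)
        self.params = {"w": rng.standard_normal((n_in, n_out)) * scale, "b": np.zeros(n_out)}
        self.grads = {"w": np.zeros_like(self.params["w"]), "b": np.zeros_like(self.params["b"])}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad_out):
        self.grads["w"] = self._x.T @ grad_out
        self.grads["b"] = grad_out.sum(axis=0)
        return grad_out @ self.params["w"].T


class ReLU(Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return grad_out * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.grads = {"gamma": np.zeros(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad_out):
        self.grads["gamma"] = (grad_out * self._xhat).sum(axis=0)
        self.grads["beta"] = grad_out.sum(axis=0)
        g = grad_out * self.params["gamma"]
        if not self._train:
            return g / self._std
        n = grad_out.shape[0]
        # full batch-stat backward
        return (g - g.mean(axis=0) - self._xhat * (g * self._xhat).mean(axis=0)) / self._std


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, y_index: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    loss = -np.mean(np.log(np.clip(probs[np.arange(n), y_index], 1e-12, None)))
    grad = probs.copy()
    grad[np.arange(n), y_index] -= 1.0
    return loss, grad / n


class SGDMomentum:
    def __init__(self, layers, lr: float, momentum: float = 0.9, weight_decay: float = 1e-4):
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers]

    def step(self):
        for layer, vel in zip(self.layers, self.velocity):
            for k in layer.params:
                g = layer.grads[k] + self.weight_decay * layer.params[k]
                vel[k] = self.momentum * vel[k] + g
                layer.params[k] -= self.lr * vel[k]


class Adam:
    def __init__(self, layers, lr: float, weight_decay: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers]
        self.t = 0

    def step(self):
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k in layer.params:
                g = layer.grads[k] + self.weight_decay * layer.params[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                mhat = m[k] / (1 - self.beta1**self.t)
                vhat = v[k] / (1 - self.beta2**self.t)
                layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def lr_at(epoch: int, schedule: list[tuple[int, float]]) -> float:
    """Learning rate active at a given epoch for a [(start_epoch, lr), ...] schedule."""
    current = schedule[0][1]
    for start, lr in schedule:
        if epoch >= start:
            current = lr
    return current
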