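"""Shallow multilayer perceptron trained by minibatch SGD with momentum.

Architecture: one or two fully connected hidden layers, each followed by
batch normalization and ReLU, then a linear softmax head (a two-logit
softmax plays the role of the sigmoid in the binary case).  Training uses
cross-entropy with weight decay, momentum 0.9, and a step learning-rate
schedule; defaults follow a 25-epoch protocol with the rate dropping by 10x
at epochs 13 and 23.  All randomness (init, batch order) flows from the
seed, so two runs with the same seed give identical predictions.
"""

from __future__ import annotations

import numpy as np

from gxplain.models import _nn
from gxplain.models.base import TrainedModel

DEFAULT_SCHEDULE = [(0, 0.1), (13, 0.01), (23, 0.001)]


class MLPModel(TrainedModel):
    def __init__(self, layers, gene_names, n_classes, seed):
        self.layers = layers
        self.model_family = "mlp"
        self.gene_names = list(gene_names)
        self.n_classes = n_classes
        self.replicate_seed = seed

    @property
    def weights(self) -> np.ndarray:
        """First-layer weight matrix, genes in rows."""
        return self.layers[0].params["w"]

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return _nn.softmax(self._forward(x, train=False))

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """d p_c / d x per sample, backpropagated in evaluation mode."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        probs = _nn.softmax(self._forward(x, train=False))
        c = target_class - 1
        # d p_c / d logits = p_c * (delta_kc - p_k)
        grad = -probs[:, [c]] * probs
        grad[:, c] += probs[:, c]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    gene_names: list[str],
    hidden_sizes: tuple[int, ...] = (64,),
    epochs: int = 25,
    batch_size: int = 32,
    learning_rate_schedule: list[tuple[int, float]] | None = None,
    momentum: float = 0.9,
    weight_decay: float = 1e-4,
    seed: int = 0,
) -> MLPModel:
    """Train a 1- or 2-hidden-layer MLP on standardized training data."""
    if len(hidden_sizes) not in (1, 2) or any(h < 1 for h in hidden_sizes):
        raise ValueError("hidden_sizes must contain 1 or 2 positive widths")
    schedule = learning_rate_schedule or DEFAULT_SCHEDULE
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    n, g = x_train.shape
    n_classes = int(y_train.max())
    y_index = y_train - 1

    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    widths = [g, *hidden_sizes]
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers.append(_nn.Dense(n_in, n_out, rng))
        layers.append(_nn.BatchNorm(n_out))
        layers.append(_nn.ReLU())
    layers.append(_nn.Dense(widths[-1], n_classes, rng))

    opt = _nn.SGDMomentum(layers, lr=schedule[0][1], momentum=momentum, weight_decay=weight_decay)
    for epoch in range(epochs):
        opt.lr = _nn.lr_at(epoch, schedule)
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = perm[start:start + batch_size]
            if batch.size < 2:
                continue  # batch statistics undefined on singleton batches
            h = x_train[batch]
            for layer in layers:
                h = layer.forward(h, train=True)
            probs = _nn.softmax(h)
            loss, grad = _nn.cross_entropy_grad(probs, y_index[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(f"MLP loss diverged (NaN/inf) at epoch {epoch}")
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step()
    return MLPModel(layers, gene_names, n_classes, seed)
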