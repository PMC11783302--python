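"""Shared model interface and evaluation metric.

Every trained model predicts class probabilities over ``1..C``.  Gradient
surfaces (d f_c / d x, needed by integrated gradients) exist for the
logistic, MLP and GNN families; per-feature gains exist for boosted trees.
"""

from __future__ import annotations

import abc

import numpy as np


class TrainedModel(abc.ABC):
    """A classifier over standardized expression matrices.

    Attributes
    ----------
    model_family
        One of ``lr_l1, lr_l2, mlp, gnn, gbt``.
    gene_names
        Feature names, in column order of the training matrix.
    replicate_seed
        The seed this replicate was trained with.
    """

    model_family: str
    gene_names: list[str]
    replicate_seed: int
    n_classes: int

    @abc.abstractmethod
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class-probability matrix, rows summing to 1."""

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class labels in ``1..C``."""
        return np.argmax(self.predict_proba(np.atleast_2d(x)), axis=1) + 1

    @property
    def has_gradient(self) -> bool:
        return hasattr(self, "input_gradient")


def balanced_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean over classes of per-class recall, in [0, 1].

    Insensitive to class imbalance; every class in ``1..C`` must appear in
    the truth vector.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    c = int(truth.max())
    recalls = []
    for cls in range(1, c + 1):
        mask = truth == cls
        if not mask.any():
            raise ValueError(f"class {cls} absent from truth labels")
        recalls.append(float(np.mean(predicted[mask] == cls)))
    return float(np.mean(recalls))
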