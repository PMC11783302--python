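"""L1/L2-regularized logistic regression with an analytic gradient surface.

Binary: ``f(x) = sigmoid(Wx + b)``; multi-class: softmax over C linear
scores.  Fitting is delegated to scikit-learn's SAGA solver (cross-entropy
plus the chosen penalty, 1000-iteration cap); the probability gradients with
respect to the input are closed-form and exposed for integrated gradients.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from gxplain.models.base import TrainedModel


class LogisticModel(TrainedModel):
    def __init__(self, weights: np.ndarray, intercepts: np.ndarray, penalty: str,
                 gene_names: list[str], n_classes: int, seed: int):
        self.weights = weights            # (1, G) binary or (C, G) multi-class
        self.intercepts = intercepts
        self.model_family = f"lr_{penalty}"
        self.gene_names = list(gene_names)
        self.n_classes = n_classes
        self.replicate_seed = seed

    def _logits(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights.T + self.intercepts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = self._logits(x)
        if self.weights.shape[0] == 1:
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """d p_c / d x per sample; ``target_class`` in 1..C."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = self.predict_proba(x)
        c = target_class - 1
        if self.weights.shape[0] == 1:
            w = self.weights[0]
            s = p[:, 1] * (1.0 - p[:, 1])
            sign = 1.0 if c == 1 else -1.0
            return sign * s[:, None] * w[None, :]
        # softmax: d p_c / dx = p_c (W_c - sum_k p_k W_k)
        wbar = p @ self.weights
        return p[:, [c]] * (self.weights[c][None, :] - wbar)


def train_logistic(
    x_train: np.ndarray,
    y_train: np.ndarray,
    gene_names: list[str],
    penalty: str = "l2",
    regularization_strength: float = 1.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> LogisticModel:
    """Fit LR+L1 or LR+L2 on standardized training data.

    ``regularization_strength`` multiplies the penalty term (sklearn's
    ``C = 1 / regularization_strength``).  Non-convergence within the
    iteration cap is a warning, not an error.
    """
    if penalty not in ("l1", "l2"):
        raise ValueError("penalty must be 'l1' or 'l2'")
    y_train = np.asarray(y_train, dtype=int)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("logistic regression needs >= 2 classes")
    if regularization_strength <= 0:
        raise ValueError("regularization_strength must be > 0")
    clf = LogisticRegression(
        l1_ratio=1.0 if penalty == "l1" else 0.0,
        C=1.0 / regularization_strength,
        solver="saga",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(np.asarray(x_train, dtype=float), y_train)
    return LogisticModel(
        weights=np.atleast_2d(clf.coef_).copy(),
        intercepts=np.atleast_1d(clf.intercept_).copy(),
        penalty=penalty,
        gene_names=gene_names,
        n_classes=int(classes.max()),
        seed=seed,
    )
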