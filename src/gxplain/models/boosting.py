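"""Gradient-boosted decision trees via XGBoost, with per-gene total gain.

Trees are built sequentially, each correcting the residual errors of the
ensemble so far.  With fixed hyperparameters the training process is
deterministic, so the family produces a single ranking (no replicates).
Defaults use a learning rate of 1.
"""

from __future__ import annotations

import numpy as np
import xgboost as xgb

from gxplain.models.base import TrainedModel


class GBTModel(TrainedModel):
    def __init__(self, booster: xgb.XGBClassifier, gene_names: list[str], n_classes: int):
        self._clf = booster
        self.model_family = "gbt"
        self.gene_names = list(gene_names)
        self.n_classes = n_classes
        self.replicate_seed = 0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = self._clf.predict_proba(x)
        if p.shape[1] != self.n_classes:  # pragma: no cover - defensive
            raise RuntimeError("unexpected probability shape from xgboost")
        return p

    @property
    def feature_importances(self) -> np.ndarray:
        """Total gain per gene across all splits; 0 for unused genes."""
        raw = self._clf.get_booster().get_score(importance_type="total_gain")
        gains = np.zeros(len(self.gene_names))
        for key, value in raw.items():
            gains[int(key[1:])] = value  # keys are 'f<index>'
        return gains


def train_gbt(
    x_train: np.ndarray,
    y_train: np.ndarray,
    gene_names: list[str],
    n_estimators: int = 50,
    max_depth: int = 3,
    learning_rate: float = 1.0,
) -> GBTModel:
    """Fit an XGBoost classifier on standardized training data."""
    y_train = np.asarray(y_train, dtype=int)
    n_classes = int(y_train.max())
    clf = xgb.XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        objective="binary:logistic" if n_classes == 2 else "multi:softprob",
        n_jobs=1,
        tree_method="hist",
        random_state=0,
        verbosity=0,
    )
    clf.fit(np.asarray(x_train, dtype=float), y_train - 1)
    return GBTModel(clf, gene_names, n_classes)
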