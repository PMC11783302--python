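"""Gene importance rankings from filter and embedded statistics.

Filter scores (classifier-independent): per-gene variance, magnitude of the
leading principal-component loading, mutual information with the class
variable, and a Welch two-sample t-test differential-expression score
``-log10(BH-adjusted p)``.  Embedded scores (integral to a trained model):
logistic-regression weight magnitudes and gradient-boosted-tree total gain.

All rankings share the :class:`GeneRanking` container: higher score = more
important, rank 1 = most important, ties broken lexicographically by gene
name (deterministic; recorded in the ranking-file header).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneRanking:
    """Per-gene importance scores from one method/replicate."""

    method_name: str
    gene_names: list[str]
    scores: np.ndarray
    replicate_id: int | None = None
    direction_note: str = "higher score = more important"
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_names),):
            raise ValueError("one score per gene required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        # stable sort on (-score, name): rank 1 = highest score
        order = sorted(range(len(self.gene_names)), key=lambda i: (-self.scores[i], self.gene_names[i]))
        self.ranks = np.empty(len(order), dtype=int)
        self.ranks[order] = np.arange(1, len(order) + 1)

    def top(self, k: int) -> list[str]:
        """The k most important gene names, most important first."""
        order = np.argsort(self.ranks)
        return [self.gene_names[i] for i in order[:k]]

    def bottom(self, k: int) -> list[str]:
        """The k least important gene names, least important first."""
        order = np.argsort(self.ranks)[::-1]
        return [self.gene_names[i] for i in order[:k]]

    def order_important_first(self) -> np.ndarray:
        """Gene column indices sorted most-important-first."""
        return np.argsort(self.ranks)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.scores))


@dataclass
class FilterStatistics:
    """Raw statistics backing the differential-expression ranking."""

    welch_t: np.ndarray
    p_values_raw: np.ndarray
    p_values_adjusted: np.ndarray
    class_pair_used: list[tuple[int, int]]
    gene_variances: np.ndarray | None = None
    first_principal_component: np.ndarray | None = None
    mutual_information: np.ndarray | None = None


def rank_variance(matrix: np.ndarray, gene_names: list[str]) -> GeneRanking:
    """Rank genes by variance across samples (population convention, 1/N).

    Ignores class labels entirely.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("variance ranking needs >= 2 samples")
    scores = matrix.var(axis=0, ddof=0)
    return GeneRanking("var", list(gene_names), scores)


def rank_pca(matrix: np.ndarray, gene_names: list[str]) -> GeneRanking:
    """Rank genes by |loading| on the first principal component.

    The leading unit eigenvector of the gene-gene covariance of the centred
    matrix; the eigenvector sign indeterminacy is harmless under the absolute
    value.  A degenerate leading eigenvalue (multiplicity > 1 within
    tolerance) makes the loadings arbitrary within the eigenspace and is
    flagged with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("PCA ranking needs >= 2 samples")
    x = matrix - matrix.mean(axis=0)
    # eigenvectors of X^T X via SVD (no G x G covariance materialized)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if len(s) > 1 and s[0] > 0 and (s[0] - s[1]) / s[0] < 1e-9:
        warnings.warn("leading eigenvalue nearly degenerate; PC1 loadings are ill-determined")
    v1 = vt[0]
    v1 = v1 / np.linalg.norm(v1)
    return GeneRanking("pca", list(gene_names), np.abs(v1))


def rank_mutual_information(
    matrix: np.ndarray,
    labels: np.ndarray,
    gene_names: list[str],
    neighbors: int = 3,
    seed: int = 0,
) -> GeneRanking:
    """Rank genes by estimated mutual information I(X_g; Y) in nats.

    Uses the k-nearest-neighbour estimator for a continuous feature against
    the discrete class variable; negative estimates are clipped to 0.
    """
    from sklearn.feature_selection import mutual_info_classif

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("MI ranking needs >= 2 classes")
    counts = np.bincount(labels)
    small = np.flatnonzero((counts > 0) & (counts < neighbors + 1))
    if small.size:
        raise ValueError(f"class {small[0]} has fewer than neighbors+1={neighbors + 1} samples")
    mi = mutual_info_classif(
        np.asarray(matrix, dtype=float), labels, n_neighbors=neighbors, random_state=seed
    )
    return GeneRanking("mi", list(gene_names), np.clip(mi, 0.0, None))


def rank_differential_expression(
    matrix: np.ndarray,
    labels: np.ndarray,
    gene_names: list[str],
) -> tuple[GeneRanking, FilterStatistics]:
    """Welch-t differential-expression ranking, score = -log10(adjusted p).

    Per gene, a Welch unequal-variance two-sample t-test between classes on
    the supplied (log-CPM) values.  With more than two classes every
    unordered class pair is tested, the minimal raw p per gene is kept (and
    the winning pair recorded), then Benjamini-Hochberg adjustment is applied
    across genes.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("differential expression needs >= 2 classes")
    counts = np.bincount(labels)[classes]
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples for Welch's t-test")

    g = matrix.shape[1]
    best_p = np.ones(g)
    best_t = np.zeros(g)
    best_pair = np.zeros((g, 2), dtype=int)
    for a, b in itertools.combinations(classes.tolist(), 2):
        xa = matrix[labels == a]
        xb = matrix[labels == b]
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=RuntimeWarning)  # constant columns
            t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
        degenerate = ~np.isfinite(t)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} genes with zero within-class variance in classes "
                f"({a},{b}); their p-values set to 1"
            )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        better = p < best_p
        best_p = np.where(better, p, best_p)
        best_t = np.where(better, t, best_t)
        best_pair[better] = (a, b)

    _, p_adj, _, _ = multipletests(best_p, method="fdr_bh")
    scores = -np.log10(np.clip(p_adj, 1e-300, None))
    ranking = GeneRanking("de_welch", list(gene_names), scores)
    statistics = FilterStatistics(
        welch_t=best_t,
        p_values_raw=best_p,
        p_values_adjusted=p_adj,
        class_pair_used=[tuple(pr) for pr in best_pair],
    )
    return ranking, statistics


def rank_lr_weights(model) -> GeneRanking:
    """Rank genes by logistic-regression weight magnitude.

    Binary: ``|W_g|``.  Multi-class: the mean over classes of ``|W_cg|``.
    """
    if model.model_family not in ("lr_l1", "lr_l2"):
        raise ValueError(f"weight ranking requires a logistic model, got {model.model_family}")
    w = np.atleast_2d(model.weights)
    if w.shape[0] == 1:
        scores = np.abs(w[0])
    else:
        scores = np.abs(w).mean(axis=0)
    return GeneRanking(
        f"{model.model_family}_weight", list(model.gene_names), scores, replicate_id=model.replicate_seed
    )


def rank_gbt_gain(model) -> GeneRanking:
    """Rank genes by total split gain in the boosted-tree ensemble.

    Genes never used in a split score exactly 0; the count of nonzero-gain
    genes is recorded on the ranking (``n_nonzero``).
    """
    if model.model_family != "gbt":
        raise ValueError(f"gain ranking requires a gbt model, got {model.model_family}")
    return GeneRanking("gbt_gain", list(model.gene_names), model.feature_importances)
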