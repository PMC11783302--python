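"""Gene filtering, CPM/log2 normalization, stratified split, standardization.

The processing chain is: ``filter_genes`` -> ``normalize`` -> ``split`` ->
``standardize``.  Gene filters remove (i) genes with any NaN, (ii) genes
whose maximal count is 0, and (iii) low-expressed genes with fewer than
``low_count_threshold`` counts in more than ``low_count_sample_fraction`` of
the samples of every class (quantifier switchable to "any class").
Normalization scales each sample's counts to a total of 10^6 (CPM) and takes
log2(1 + cpm).  The split is stratified by class; standardization z-scores
every column with means and standard deviations computed from the training
samples only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from gxplain.datasets import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class ProcessedDataset:
    """Filtered, log-CPM, train-standardized matrix with its split."""

    matrix: np.ndarray
    kept_gene_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray
    standardizer_means: np.ndarray
    standardizer_stds: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def x_train(self) -> np.ndarray:
        return self.matrix[self.train_index]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels[self.train_index]

    @property
    def x_test(self) -> np.ndarray:
        return self.matrix[self.test_index]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels[self.test_index]

    def inverse_transform(self, standardized: np.ndarray) -> np.ndarray:
        """Undo the z-scoring (back to log-CPM units)."""
        return standardized * self.standardizer_stds + self.standardizer_means

    def subset_genes(self, keep: np.ndarray) -> "ProcessedDataset":
        keep = np.asarray(keep)
        return replace(
            self,
            matrix=self.matrix[:, keep],
            kept_gene_names=[self.kept_gene_names[i] for i in keep],
            standardizer_means=self.standardizer_means[keep],
            standardizer_stds=self.standardizer_stds[keep],
        )


def filter_genes(
    data: ExpressionDataset,
    low_count_threshold: float = 5,
    low_count_sample_fraction: float = 0.75,
    low_count_quantifier: str = "every",
) -> ExpressionDataset:
    """Apply the three gene-removal rules, in order, and log removal counts.

    Rule (iii) removes a gene when, in EVERY class (default quantifier),
    strictly more than ``low_count_sample_fraction`` of that class's samples
    have a count below ``low_count_threshold``.  The "any" quantifier removes
    when the condition holds in at least one class, discarding genes
    expressed in a single class.
    """
    if low_count_quantifier not in ("every", "any"):
        raise ValueError("low_count_quantifier must be 'every' or 'any'")
    counts = data.counts
    keep = np.ones(data.n_genes, dtype=bool)

    nan_mask = np.isnan(counts).any(axis=0)
    keep &= ~nan_mask

    with np.errstate(invalid="ignore"):
        zero_mask = np.nanmax(np.where(np.isnan(counts), 0.0, counts), axis=0) == 0
    zero_mask &= keep
    keep &= ~zero_mask

    low_per_class = []
    for c in range(1, data.n_classes + 1):
        rows = counts[data.labels == c]
        frac_low = np.mean(np.nan_to_num(rows, nan=0.0) < low_count_threshold, axis=0)
        low_per_class.append(frac_low > low_count_sample_fraction)
    low_per_class = np.array(low_per_class)
    low_mask = low_per_class.all(axis=0) if low_count_quantifier == "every" else low_per_class.any(axis=0)
    low_mask &= keep
    keep &= ~low_mask

    logger.info(
        "gene filter: %d NaN, %d all-zero, %d low-count removed; %d kept",
        int(nan_mask.sum()), int(zero_mask.sum()), int(low_mask.sum()), int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("all genes removed by filtering")
    return data.subset_genes(np.flatnonzero(keep))


def normalize(data: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Counts-per-million scaling then log2(pseudocount + cpm), per sample."""
    totals = data.counts.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"sample {data.sample_ids[zero[0]]!r} has zero total count")
    cpm = data.counts * (1e6 / totals[:, None])
    return replace(data, counts=np.log2(pseudocount + cpm))


def split(
    data: ExpressionDataset,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; deterministic under ``seed``.

    Per-class train counts are round-half-up of ``fraction * class size``,
    then adjusted by +-1 on the largest classes so the global train count
    equals round-half-up of ``fraction * N``; every class keeps at least one
    sample on each side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sizes = {c: int((data.labels == c).sum()) for c in range(1, data.n_classes + 1)}
    for c, sz in sizes.items():
        if sz < 2:
            raise ValueError(f"class {c} has {sz} sample(s); cannot split")

    def round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    n_train = {c: min(max(round_half_up(train_fraction * sz), 1), sz - 1) for c, sz in sizes.items()}
    target = min(
        max(round_half_up(train_fraction * data.n_samples), data.n_classes),
        data.n_samples - data.n_classes,
    )
    order = sorted(sizes, key=lambda c: -sizes[c])
    i = 0
    while sum(n_train.values()) != target:
        c = order[i % len(order)]
        if sum(n_train.values()) < target and n_train[c] < sizes[c] - 1:
            n_train[c] += 1
        elif sum(n_train.values()) > target and n_train[c] > 1:
            n_train[c] -= 1
        i += 1

    train_parts, test_parts = [], []
    for c in range(1, data.n_classes + 1):
        idx = np.flatnonzero(data.labels == c)
        perm = rng.permutation(idx)
        train_parts.append(np.sort(perm[: n_train[c]]))
        test_parts.append(np.sort(perm[n_train[c]:]))
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def standardize(
    data: ExpressionDataset,
    train_index: np.ndarray,
    test_index: np.ndarray,
) -> ProcessedDataset:
    """Z-score all samples with train-derived means and stds (population).

    Standard deviations below 1e-12 are replaced by 1 with a warning so the
    transform stays invertible.
    """
    train_index = np.asarray(train_index)
    test_index = np.asarray(test_index)
    if np.intersect1d(train_index, test_index).size:
        raise ValueError("train and test indices overlap")
    x = data.counts
    means = x[train_index].mean(axis=0)
    stds = x[train_index].std(axis=0, ddof=0)
    tiny = stds < 1e-12
    if tiny.any():
        warnings.warn(f"{int(tiny.sum())} constant training columns; std set to 1")
        stds = np.where(tiny, 1.0, stds)
    return ProcessedDataset(
        matrix=(x - means) / stds,
        kept_gene_names=list(data.gene_names),
        sample_ids=list(data.sample_ids),
        labels=data.labels.copy(),
        train_index=train_index,
        test_index=test_index,
        standardizer_means=means,
        standardizer_stds=stds,
    )


def prepare(
    data: ExpressionDataset,
    train_fraction: float = 0.6,
    seed: int = 0,
    low_count_threshold: float = 5,
    low_count_sample_fraction: float = 0.75,
    low_count_quantifier: str = "every",
    pseudocount: float = 1.0,
) -> ProcessedDataset:
    """Run the full chain filter -> normalize -> split -> standardize."""
    filtered = filter_genes(
        data,
        low_count_threshold=low_count_threshold,
        low_count_sample_fraction=low_count_sample_fraction,
        low_count_quantifier=low_count_quantifier,
    )
    logcpm = normalize(filtered, pseudocount=pseudocount)
    train_idx, test_idx = split(logcpm, train_fraction=train_fraction, seed=seed)
    return standardize(logcpm, train_idx, test_idx)
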