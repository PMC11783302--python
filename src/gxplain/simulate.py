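"""Synthetic RNA-seq count matrices with planted class structure.

Counts are negative-binomial (mean mu, variance mu + dispersion * mu^2), the
standard overdispersed model for bulk RNA-seq reads.  Per-gene baseline
log2-means are uniform over a configurable range so both low- and
high-expression regimes occur (exercising the low-count gene filter).
Differential expression is planted per class by multiplying the mean by
``2**log2_fold_change`` for a disjoint set of genes per class.  Redundant
correlated gene blocks share a per-sample Gaussian latent factor on the
log-mean scale; the factor loading is solved from the target pairwise
Pearson correlation of the resulting counts (closed form below), so block
correlation is controllable while counts stay integer-valued.

The generator defines the study conditions every downstream stage is tested
under; nothing here depends on external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gxplain.datasets import ExpressionDataset, GeneSetCollection


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure count simulation.

    Defaults give a two-class, imbalanced, 10^4-gene problem with a modest
    planted effect, in the spirit of public tumour/normal compendia where
    class sizes are unequal and only a small fraction of genes is planted as
    differentially expressed.
    """

    n_samples_per_class: tuple[int, ...] = (100, 100)
    n_genes: int = 10_000
    n_de_genes_per_class: int = 20
    log2_fold_change: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (0.0, 8.0)  # log2 scale
    n_redundant_blocks: int = 0
    block_size: int = 10
    block_correlation: float = 0.8
    block_log2_fold_change: float = 0.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.n_samples_per_class)

    def validate(self) -> None:
        if not self.n_samples_per_class or any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("n_samples_per_class must be positive integers")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_de_genes_per_class < 0 or self.n_redundant_blocks < 0:
            raise ValueError("planted counts must be nonnegative")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if self.log2_fold_change < 0:
            raise ValueError("log2_fold_change must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must be in [0, 1)")
        planted = (
            self.n_de_genes_per_class * self.n_classes
            + self.n_redundant_blocks * self.block_size
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes}): infeasible config"
            )
        rho, phi = self.block_correlation, self.nb_dispersion
        if rho > 0 and rho * (1.0 + phi) >= 1.0:
            raise ValueError(
                "block_correlation unattainable: need block_correlation * (1 + dispersion) < 1"
            )


@dataclass
class PlantedTruth:
    """Ground truth of the simulation, for recovery scoring."""

    de_gene_indices_by_class: dict[int, set[int]]
    redundant_block_membership: dict[int, int]
    true_log2_fold_changes: np.ndarray
    block_class: dict[int, int] = field(default_factory=dict)

    def all_de_indices(self) -> set[int]:
        out: set[int] = set()
        for s in self.de_gene_indices_by_class.values():
            out |= s
        return out


def gene_name(i: int) -> str:
    return f"G{i + 1:06d}"


def _block_loading(rho: float, dispersion: float) -> float:
    """Latent-factor loading lambda giving pairwise count correlation ~ rho.

    For counts NB(mu_n = m * exp(lambda * z_n)) with shared z ~ N(0,1) and
    large m, Corr = (e^{l^2} - 1) / ((1 + phi) e^{l^2} - 1); solving for
    e^{l^2} gives (1 - rho) / (1 - rho (1 + phi)).
    """
    if rho <= 0:
        return 0.0
    e = (1.0 - rho) / (1.0 - rho * (1.0 + dispersion))
    return math.sqrt(math.log(e))


def generate_counts(config: SyntheticConfig) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw a count matrix with planted DE genes and redundant blocks.

    Deterministic for a fixed config (bit-identical counts).  Gene index
    layout: the first ``n_de_genes_per_class * C`` genes are the per-class DE
    genes (class 1 first), the next ``n_redundant_blocks * block_size`` genes
    form the blocks, the remainder is background.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c_count = config.n_classes
    n = sum(config.n_samples_per_class)
    g = config.n_genes

    labels = np.concatenate(
        [np.full(k, c + 1, dtype=int) for c, k in enumerate(config.n_samples_per_class)]
    )

    low, high = config.baseline_mean_log_range
    base_log2 = rng.uniform(low, high, size=g)

    de_by_class: dict[int, set[int]] = {}
    true_lfc = np.zeros(g)
    cursor = 0
    for c in range(1, c_count + 1):
        idx = set(range(cursor, cursor + config.n_de_genes_per_class))
        de_by_class[c] = idx
        cursor += config.n_de_genes_per_class
        for i in idx:
            true_lfc[i] = config.log2_fold_change

    block_membership: dict[int, int] = {}
    block_class: dict[int, int] = {}
    block_ids = []
    for b in range(config.n_redundant_blocks):
        members = list(range(cursor, cursor + config.block_size))
        cursor += config.block_size
        for i in members:
            block_membership[i] = b
        cls = b % c_count + 1  # round-robin class assignment for block signal
        block_class[b] = cls
        block_ids.append(members)
        if config.block_log2_fold_change > 0:
            for i in members:
                true_lfc[i] = config.block_log2_fold_change

    # per-sample, per-gene log2 mean
    log2_mu = np.tile(base_log2, (n, 1))
    for c, idx in de_by_class.items():
        if idx:
            rows = labels == c
            cols = sorted(idx)
            log2_mu[np.ix_(rows, cols)] += config.log2_fold_change
    for b, members in enumerate(block_ids):
        if config.block_log2_fold_change > 0:
            rows = labels == block_class[b]
            log2_mu[np.ix_(rows, members)] += config.block_log2_fold_change

    mu = np.exp2(log2_mu)
    lam = _block_loading(config.block_correlation, config.nb_dispersion)
    if lam > 0:
        z = rng.standard_normal((n, config.n_redundant_blocks))
        factor = np.exp(lam * z - lam**2 / 2.0)  # unit mean multiplicative factor
        for b, members in enumerate(block_ids):
            mu[:, members] *= factor[:, [b]]

    # NB via gamma-Poisson: shape r = 1/dispersion, scale mu/r
    r = 1.0 / config.nb_dispersion
    shaped = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(shaped).astype(float)

    data = ExpressionDataset(
        counts=counts,
        gene_names=[gene_name(i) for i in range(g)],
        sample_ids=[f"S{j + 1:05d}" for j in range(n)],
        labels=labels,
    )
    truth = PlantedTruth(
        de_gene_indices_by_class=de_by_class,
        redundant_block_membership=block_membership,
        true_log2_fold_changes=true_lfc,
        block_class=block_class,
    )
    return data, truth


def generate_toy_gmt(
    truth: PlantedTruth,
    n_decoy_sets: int,
    seed: int,
    n_genes: int | None = None,
    set_size: int = 50,
) -> GeneSetCollection:
    """Build a gene-set collection keyed to the planted truth.

    One set per class holding that class's planted DE genes padded with
    random background genes up to ``set_size``, plus ``n_decoy_sets`` fully
    random sets of the same size.  Deterministic under ``seed``.
    """
    if not truth.de_gene_indices_by_class or not truth.all_de_indices():
        raise ValueError("planted truth has no DE genes; nothing to build sets from")
    rng = np.random.default_rng(seed)
    if n_genes is None:
        n_genes = int(truth.true_log2_fold_changes.shape[0])
    universe = np.arange(n_genes)
    sets: dict[str, tuple[str, list[str]]] = {}
    for c, idx in sorted(truth.de_gene_indices_by_class.items()):
        if not idx:
            continue
        members = sorted(idx)
        pool = np.setdiff1d(universe, np.array(members))
        pad = rng.choice(pool, size=max(0, set_size - len(members)), replace=False)
        genes = [gene_name(i) for i in members] + [gene_name(i) for i in sorted(pad)]
        sets[f"PLANTED_CLASS_{c}"] = (f"planted DE genes of class {c}", genes)
    for d in range(n_decoy_sets):
        pick = rng.choice(universe, size=min(set_size, n_genes), replace=False)
        sets[f"DECOY_{d + 1:03d}"] = ("random decoy set", [gene_name(i) for i in sorted(pick)])
    return GeneSetCollection(sets)
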