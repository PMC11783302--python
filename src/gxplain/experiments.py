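"""Experiment orchestration: masking (0), retraining (1/2), overlaps, diagnostics.

Experiment 0 masks genes in a trained model without retraining and reports
PGI/PGU averaged over correctly classified training samples, with
cross-replicate mean and standard deviation.  Experiments 1 and 2 retrain a
model family from scratch on the ``g`` highest- (or lowest-, or randomly
selected) ranked genes over a grid of ``g`` and report held-out balanced
accuracy.  Overlap matrices compare top-k gene lists across methods and
replicates.  The t-statistic diagnostic correlates any ranking with the
Welch |t| vector (Spearman) and contrasts the |t| distribution of its top
genes with a random draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gxplain.attributions import prediction_gap
from gxplain.models import (
    balanced_accuracy,
    build_correlation_graph,
    train_gbt,
    train_gnn,
    train_logistic,
    train_mlp,
)
from gxplain.preprocess import ProcessedDataset
from gxplain.rankers import FilterStatistics, GeneRanking

SELECTIONS = ("top", "bottom", "random")


@dataclass
class OverlapMatrix:
    """Pairwise top-k overlap percentages between ranking methods.

    Lower triangle: top ``k_small`` overlap; upper triangle and diagonal:
    top ``k_large``.  Diagonal entries are within-method replicate overlaps
    (100 by design for single-ranking methods).  Methods whose nonzero-score
    gene count is below k are masked (NaN).
    """

    methods: list[str]
    top_small_lower: np.ndarray
    top_large_upper: np.ndarray
    diagonal: np.ndarray
    replicate_counts: dict[str, int]
    k_small: int
    k_large: int

    def combined(self) -> np.ndarray:
        """Single matrix: lower = top-k_small, upper + diag = top-k_large."""
        m = len(self.methods)
        out = np.full((m, m), np.nan)
        for i in range(m):
            out[i, i] = self.diagonal[i]
            for j in range(i):
                out[i, j] = self.top_small_lower[i, j]
                out[j, i] = self.top_large_upper[j, i]
        return out


@dataclass
class RetrainCurve:
    """Balanced accuracy vs number of retained genes."""

    gene_count_grid: np.ndarray
    balanced_accuracy_mean: np.ndarray
    balanced_accuracy_std: np.ndarray
    selection: str
    source_ranking_method: str
    model_family: str


@dataclass
class Experiment0Result:
    """Per-replicate and aggregate PGI/PGU."""

    pgi_per_replicate: np.ndarray
    pgu_per_replicate: np.ndarray
    pgi_mean: float
    pgi_std: float
    pgu_mean: float
    pgu_std: float

    @property
    def maskable_percent(self) -> float:
        """100 - PGI: percentage of well-ranked genes maskable before
        disturbing the model."""
        return 100.0 * (1.0 - self.pgi_mean)


def _mean_topk_overlap(lists_a: list[list[str]], lists_b: list[list[str]], k: int,
                       within: bool = False) -> float:
    pairs = []
    if within:
        n = len(lists_a)
        if n == 1:
            return 100.0
        for i in range(n):
            for j in range(i + 1, n):
                pairs.append((lists_a[i], lists_a[j]))
    else:
        for a in lists_a:
            for b in lists_b:
                pairs.append((a, b))
    vals = [100.0 * len(set(a) & set(b)) / k for a, b in pairs]
    return float(np.mean(vals))


def overlap_matrix(
    rankings: dict[str, list[GeneRanking]],
    k_small: int = 10,
    k_large: int = 100,
) -> OverlapMatrix:
    """Average top-k overlap over all replicate pairs, per method pair."""
    methods = list(rankings)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to compare")
    universe = None
    for reps in rankings.values():
        for r in reps:
            names = frozenset(r.gene_names)
            if universe is None:
                universe = names
            elif names != universe:
                raise ValueError("rankings cover different gene universes")

    def usable(method: str, k: int) -> bool:
        return all(r.n_nonzero >= k for r in rankings[method])

    tops = {
        m: {k: [r.top(k) for r in rankings[m]] for k in (k_small, k_large)}
        for m in methods
    }
    n = len(methods)
    lower = np.full((n, n), np.nan)
    upper = np.full((n, n), np.nan)
    diag = np.full(n, np.nan)
    for i, mi in enumerate(methods):
        if usable(mi, k_large):
            diag[i] = _mean_topk_overlap(tops[mi][k_large], [], k_large, within=True)
        for j, mj in enumerate(methods):
            if j < i and usable(mi, k_small) and usable(mj, k_small):
                lower[i, j] = _mean_topk_overlap(tops[mi][k_small], tops[mj][k_small], k_small)
            if j > i and usable(mi, k_large) and usable(mj, k_large):
                upper[i, j] = _mean_topk_overlap(tops[mi][k_large], tops[mj][k_large], k_large)
    return OverlapMatrix(
        methods=methods,
        top_small_lower=lower,
        top_large_upper=upper,
        diagonal=diag,
        replicate_counts={m: len(rankings[m]) for m in methods},
        k_small=k_small,
        k_large=k_large,
    )


def _retrain(
    processed: ProcessedDataset,
    model_family: str,
    seed: int,
    edge_budget: int | None = None,
    **kwargs,
):
    x, y = processed.x_train, processed.y_train
    names = processed.kept_gene_names
    if model_family in ("lr_l1", "lr_l2"):
        return train_logistic(x, y, names, penalty=model_family[-2:], seed=seed, **kwargs)
    if model_family == "mlp":
        return train_mlp(x, y, names, seed=seed, **kwargs)
    if model_family == "gnn":
        # sparse default: spurious noise-correlation edges smear class signal
        budget = edge_budget or max(1, processed.n_genes // 4)
        graph = build_correlation_graph(x, budget)
        return train_gnn(x, y, names, graph, seed=seed, **kwargs)
    if model_family == "gbt":
        return train_gbt(x, y, names, **kwargs)
    raise ValueError(f"unknown model family {model_family!r}")


def train_model(processed: ProcessedDataset, model_family: str, seed: int = 0,
                edge_budget: int | None = None, **kwargs):
    """Train one model family on the processed dataset (full gene set)."""
    return _retrain(processed, model_family, seed, edge_budget=edge_budget, **kwargs)


def run_experiment_1_2(
    processed: ProcessedDataset,
    rankings: list[GeneRanking],
    model_family: str,
    grid: list[int] | None = None,
    selection: str = "top",
    seeds: list[int] | None = None,
    edge_budget: int | None = None,
    **train_kwargs,
) -> RetrainCurve:
    """Retrain on gene subsets chosen from a ranking; held-out accuracy.

    ``selection='top'`` is experiment 1 (highest-ranked genes),
    ``'bottom'`` experiment 2 (lowest-ranked), ``'random'`` the random
    control.  Each ranking replicate is paired with one retraining seed;
    the curve reports mean and std over those pairs.
    """
    if selection not in SELECTIONS:
        raise ValueError(f"selection must be one of {SELECTIONS}")
    g_total = processed.n_genes
    if grid is None:
        grid = [g for g in (1, 5, 10, 50, 100, 500, 1000) if g <= g_total]
    if any(g > g_total for g in grid):
        raise ValueError("grid values must be <= number of genes")
    seeds = seeds or [r.replicate_id or 0 for r in rankings]
    pairs = list(zip(rankings, seeds))

    name_to_col = {n: i for i, n in enumerate(processed.kept_gene_names)}
    means, stds = [], []
    for g in grid:
        accs = []
        for ranking, seed in pairs:
            if selection == "top":
                genes = ranking.top(g)
            elif selection == "bottom":
                genes = ranking.bottom(g)
            else:
                rng = np.random.default_rng(seed)
                genes = [processed.kept_gene_names[i]
                         for i in rng.choice(g_total, size=g, replace=False)]
            cols = np.array([name_to_col[n] for n in genes])
            if model_family == "gnn" and cols.size < 2:
                raise ValueError("GNN retraining needs >= 2 genes")
            sub = processed.subset_genes(cols)
            model = _retrain(sub, model_family, seed, edge_budget=edge_budget, **train_kwargs)
            accs.append(balanced_accuracy(model.predict(sub.x_test), sub.y_test))
        means.append(np.mean(accs))
        stds.append(np.std(accs))
    return RetrainCurve(
        gene_count_grid=np.array(grid),
        balanced_accuracy_mean=np.array(means),
        balanced_accuracy_std=np.array(stds),
        selection=selection,
        source_ranking_method=rankings[0].method_name,
        model_family=model_family,
    )


def run_experiment_0(
    models: list,
    rankings: list[GeneRanking],
    processed: ProcessedDataset,
    reference: np.ndarray,
    max_samples: int | None = 25,
    seed: int = 0,
    stride: int = 1,
) -> Experiment0Result:
    """PGI/PGU averaged over correctly classified training samples.

    ``models`` and ``rankings`` are paired per replicate.  Per replicate the
    mean PGI and PGU over (a seeded subsample of) correctly classified
    training samples is computed; the aggregate is the cross-replicate mean
    and standard deviation.
    """
    if len(models) != len(rankings):
        raise ValueError("one ranking per model replicate required")
    rng = np.random.default_rng(seed)
    pgi_rep, pgu_rep = [], []
    x, y = processed.x_train, processed.y_train
    for model, ranking in zip(models, rankings):
        predicted = model.predict(x)
        idx = np.flatnonzero(predicted == y)
        if idx.size == 0:
            raise ValueError("no correctly classified training samples")
        if max_samples is not None and idx.size > max_samples:
            idx = np.sort(rng.choice(idx, size=max_samples, replace=False))
        pgis, pgus = [], []
        for i in idx:
            target = int(y[i])
            pgis.append(prediction_gap(model, x[i], ranking, "important_first",
                                       reference, target, stride=stride).pg_value)
            pgus.append(prediction_gap(model, x[i], ranking, "unimportant_first",
                                       reference, target, stride=stride).pg_value)
        pgi_rep.append(np.mean(pgis))
        pgu_rep.append(np.mean(pgus))
    pgi_rep, pgu_rep = np.array(pgi_rep), np.array(pgu_rep)
    return Experiment0Result(
        pgi_per_replicate=pgi_rep,
        pgu_per_replicate=pgu_rep,
        pgi_mean=float(pgi_rep.mean()),
        pgi_std=float(pgi_rep.std()),
        pgu_mean=float(pgu_rep.mean()),
        pgu_std=float(pgu_rep.std()),
    )


def tstat_correlation(
    ranking: GeneRanking,
    welch: FilterStatistics,
    welch_gene_names: list[str],
    top_k: int = 100,
    seed: int = 0,
) -> dict:
    """Spearman correlation of a ranking's scores with |Welch t|.

    Also contrasts the mean |t| of the ranking's top ``top_k`` genes with a
    seeded random draw of the same size (the sanity check for rankings whose
    top genes look statistically unremarkable).
    """
    if set(ranking.gene_names) != set(welch_gene_names):
        raise ValueError("ranking and t-statistics cover different gene universes")
    t_by_name = dict(zip(welch_gene_names, np.abs(welch.welch_t)))
    t_aligned = np.array([t_by_name[n] for n in ranking.gene_names])
    if np.ptp(ranking.scores) == 0 or np.ptp(t_aligned) == 0:
        raise ValueError("constant scores: Spearman correlation undefined")
    rho, pval = stats.spearmanr(ranking.scores, t_aligned)
    top_t = np.array([t_by_name[n] for n in ranking.top(top_k)])
    rng = np.random.default_rng(seed)
    random_t = t_aligned[rng.choice(len(t_aligned), size=min(top_k, len(t_aligned)), replace=False)]
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "top_mean_abs_t": float(top_t.mean()),
        "random_mean_abs_t": float(random_t.mean()),
    }
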