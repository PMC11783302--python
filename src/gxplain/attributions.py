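"""Integrated-gradients attributions and prediction-gap fidelity metrics.

Integrated gradients assigns gene ``g`` in sample ``x`` the local score

    phi_g(x) = (x_g - x'_g) * integral_0^1  d f_c / d x_g  at  x' + a (x - x')  da

against a baseline ``x'``, approximated by a midpoint Riemann sum.  The
attributions satisfy completeness: they sum to ``f_c(x) - f_c(x')`` up to
integration error.  Local scores are aggregated per class by averaging the
L2-normalized absolute score vectors of correctly classified training
samples, and globally by averaging the class vectors.

Prediction gaps quantify ranking fidelity: genes are masked progressively
(replaced by the reference value) in a given order and

    PG = (1/G) * sum_m  max(f_c(x) - f_c(x_masked_m), 0) / f_c(x)

is the normalized area of the prediction drop.  Masking most-important-first
gives PGI, least-important-first gives PGU; for a faithful ranking PGI is
large and PGU small (PGU estimates the fraction of genes the model needs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gxplain.rankers import GeneRanking

MASKING_ORDERS = ("important_first", "unimportant_first", "random")


@dataclass
class AttributionResult:
    """Local, per-class, and global integrated-gradients scores."""

    local_scores: np.ndarray  # (n_samples_used, G)
    baseline: np.ndarray
    target_class: int
    n_steps: int
    samples_used: np.ndarray
    class_scores: np.ndarray | None = None
    global_scores: np.ndarray | None = None
    completeness_residuals: np.ndarray | None = None


@dataclass
class PGCurves:
    """Model outputs under progressive masking, plus the PG scalar."""

    masking_order: str
    per_fraction_outputs: np.ndarray  # f_c(x_masked_m), m = 0..G
    pg_value: float
    reference: np.ndarray
    target_class: int


def integrated_gradients(
    model,
    sample: np.ndarray,
    baseline: np.ndarray,
    target_class: int,
    n_steps: int = 128,
) -> tuple[np.ndarray, float]:
    """Midpoint-rule integrated gradients for one sample.

    Returns the per-gene local scores and the completeness residual
    ``|sum_g phi_g - (f_c(x) - f_c(x'))|``.
    """
    if not model.has_gradient:
        raise TypeError(
            f"integrated gradients needs a gradient-based model, not {model.model_family}"
        )
    sample = np.asarray(sample, dtype=float).ravel()
    baseline = np.asarray(baseline, dtype=float).ravel()
    if sample.shape != baseline.shape:
        raise ValueError("sample and baseline dimensions differ")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    path = baseline[None, :] + alphas[:, None] * (sample - baseline)[None, :]
    grads = model.input_gradient(path, target_class)
    scores = (sample - baseline) * grads.mean(axis=0)
    c = target_class - 1
    f_x = model.predict_proba(sample[None, :])[0, c]
    f_b = model.predict_proba(baseline[None, :])[0, c]
    residual = float(abs(scores.sum() - (f_x - f_b)))
    return scores, residual


def aggregate_class_scores(local_scores: np.ndarray) -> np.ndarray:
    """Average of L2-normalized |local| vectors over a class's samples.

    Samples whose attribution vector is all zero are dropped with a warning
    (their norm is undefined).
    """
    local_scores = np.atleast_2d(np.asarray(local_scores, dtype=float))
    norms = np.linalg.norm(local_scores, axis=1)
    ok = norms > 0
    if not ok.any():
        raise ValueError("no sample has a nonzero attribution vector")
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} all-zero attribution vectors excluded from aggregation")
    return (np.abs(local_scores[ok]) / norms[ok, None]).mean(axis=0)


def aggregate_global(class_scores: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Mean over classes of the per-class score vectors (identity for C=1)."""
    stacked = np.atleast_2d(np.asarray(class_scores, dtype=float))
    if stacked.ndim != 2:
        raise ValueError("class score vectors must share a common length")
    return stacked.mean(axis=0)


def default_baseline(processed, binary_normal_class: int = 1) -> np.ndarray:
    """Baseline x': mean of normal-class training samples (binary) or of all
    training samples (multi-class)."""
    x, y = processed.x_train, processed.y_train
    if processed.n_classes == 2:
        return x[y == binary_normal_class].mean(axis=0)
    return x.mean(axis=0)


def compute_ig_ranking(
    model,
    processed,
    n_steps: int = 128,
    baseline: np.ndarray | None = None,
    target_classes: list[int] | None = None,
    binary_target_class: int = 2,
    max_samples_per_class: int | None = None,
    seed: int = 0,
) -> tuple[GeneRanking, AttributionResult]:
    """Global IG gene ranking from correctly classified training samples.

    For binary tasks the scores are computed on the tumour (non-reference)
    class only; for multi-class tasks on every class, averaged.  A cap on
    samples per class (seeded subsample) bounds runtime on large datasets.
    """
    if baseline is None:
        baseline = default_baseline(processed)
    if target_classes is None:
        target_classes = [binary_target_class] if processed.n_classes == 2 else list(
            range(1, processed.n_classes + 1)
        )
    rng = np.random.default_rng(seed)
    x, y = processed.x_train, processed.y_train
    predicted = model.predict(x)
    class_vectors = []
    all_local, all_resid, used = [], [], []
    for c in target_classes:
        idx = np.flatnonzero((y == c) & (predicted == c))
        if idx.size == 0:
            raise ValueError(f"no correctly classified training samples in class {c}")
        if max_samples_per_class is not None and idx.size > max_samples_per_class:
            idx = np.sort(rng.choice(idx, size=max_samples_per_class, replace=False))
        locals_c = np.empty((idx.size, x.shape[1]))
        for row, i in enumerate(idx):
            locals_c[row], residual = integrated_gradients(model, x[i], baseline, c, n_steps)
            all_resid.append(residual)
        class_vectors.append(aggregate_class_scores(locals_c))
        all_local.append(locals_c)
        used.append(idx)
    global_scores = aggregate_global(class_vectors)
    result = AttributionResult(
        local_scores=np.vstack(all_local),
        baseline=baseline,
        target_class=target_classes[0] if len(target_classes) == 1 else -1,
        n_steps=n_steps,
        samples_used=np.concatenate(used),
        class_scores=np.vstack(class_vectors),
        global_scores=global_scores,
        completeness_residuals=np.array(all_resid),
    )
    ranking = GeneRanking(
        f"ig_{model.model_family}",
        list(processed.kept_gene_names),
        global_scores,
        replicate_id=model.replicate_seed,
    )
    return ranking, result


def prediction_gap(
    model,
    sample: np.ndarray,
    ranking: GeneRanking,
    order: str,
    reference: np.ndarray,
    target_class: int | None = None,
    seed: int = 0,
    stride: int = 1,
) -> PGCurves:
    """Prediction-gap curve for one sample under progressive masking.

    ``order`` is ``important_first`` (PGI), ``unimportant_first`` (PGU) or
    ``random`` (seeded permutation).  Masked genes take the reference value.
    A ``stride > 1`` evaluates every stride-th mask count; the scalar is then
    computed on the strided grid and is approximate.
    """
    if order not in MASKING_ORDERS:
        raise ValueError(f"order must be one of {MASKING_ORDERS}")
    sample = np.asarray(sample, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    g = sample.size
    if order == "important_first":
        gene_order = ranking.order_important_first()
    elif order == "unimportant_first":
        gene_order = ranking.order_important_first()[::-1]
    else:
        gene_order = np.random.default_rng(seed).permutation(g)

    if target_class is None:
        target_class = int(model.predict(sample[None, :])[0])
    c = target_class - 1

    m_grid = np.arange(0, g + 1, stride)
    if m_grid[-1] != g:
        m_grid = np.append(m_grid, g)
    masked = np.tile(sample, (len(m_grid), 1))
    for row, m in enumerate(m_grid):
        cols = gene_order[:m]
        masked[row, cols] = reference[cols]
    outputs = model.predict_proba(masked)[:, c]
    f_x = outputs[0]
    if f_x <= 0:
        raise ValueError("f_c(x) = 0: prediction gap undefined")
    drops = np.maximum(f_x - outputs[1:], 0.0) / f_x
    pg = float(drops.mean())
    return PGCurves(
        masking_order=order,
        per_fraction_outputs=outputs,
        pg_value=pg,
        reference=reference,
        target_class=target_class,
    )
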