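"""End-to-end orchestration: data -> preprocess -> train -> rank -> evaluate.

A :class:`RunConfig` (usually loaded from YAML) fully determines a run: the
data source (synthetic generator parameters or file paths), preprocessing
parameters, model families with their replicate seeds, experiment grids and
ORA settings.  ``run_full_pipeline`` executes every stage, writing CSV/TSV
tables plus a manifest (config hash, seeds, package version) into the output
directory; deterministic stages are bit-identical across reruns of the same
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import gxplain
from gxplain.attributions import compute_ig_ranking, default_baseline
from gxplain.datasets import read_expression, read_gmt, write_ranking
from gxplain.experiments import (
    overlap_matrix,
    run_experiment_0,
    run_experiment_1_2,
    train_model,
    tstat_correlation,
)
from gxplain.models import MODEL_FAMILIES, balanced_accuracy
from gxplain.ora import ora_report
from gxplain.preprocess import prepare
from gxplain.rankers import (
    rank_differential_expression,
    rank_gbt_gain,
    rank_lr_weights,
    rank_mutual_information,
    rank_pca,
    rank_variance,
)
from gxplain.simulate import SyntheticConfig, generate_counts, generate_toy_gmt

logger = logging.getLogger(__name__)

GRADIENT_FAMILIES = ("lr_l1", "lr_l2", "mlp", "gnn")
FILTER_METHODS = ("var", "pca", "mi", "de")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    matrix_path: str | None = None
    labels_path: str | None = None
    gmt_path: str | None = None
    train_fraction: float = 0.6
    low_count_threshold: float = 5
    low_count_sample_fraction: float = 0.75
    pseudocount: float = 1.0
    model_families: tuple[str, ...] = ("lr_l1", "lr_l2", "mlp", "gnn", "gbt")
    replicate_seeds: tuple[int, ...] = (0, 1)
    edge_budget: int | None = None
    ig_steps: int = 64
    pg_max_samples: int = 10
    pg_stride: int = 1
    retrain_family: str = "lr_l2"
    retrain_grid: tuple[int, ...] | None = None
    ora_top_n: int = 100
    ora_q_threshold: float = 0.05
    ora_decoy_sets: int = 20
    model_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [m for m in self.model_families if m not in MODEL_FAMILIES]
        if unknown:
            raise ConfigError(f"unknown model families: {unknown}")
        if self.retrain_family not in MODEL_FAMILIES:
            raise ConfigError(f"unknown retrain family: {self.retrain_family!r}")
        if not self.replicate_seeds:
            raise ConfigError("replicate_seeds must be nonempty")
        if (self.matrix_path is None) != (self.labels_path is None):
            raise ConfigError("matrix_path and labels_path must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("model_families", "replicate_seeds", "retrain_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """A desk-scale configuration: 2 classes, 1000 genes, 100 samples/class,
    with planted DE genes and redundant signal blocks."""
    return RunConfig(
        seed=seed,
        synthetic={
            "n_samples_per_class": (100, 100),
            "n_genes": 1000,
            "n_de_genes_per_class": 20,
            "log2_fold_change": 2.0,
            "n_redundant_blocks": 5,
            "block_size": 10,
            "block_correlation": 0.8,
            "block_log2_fold_change": 1.5,
            "seed": seed,
        },
        replicate_seeds=(0, 1),
        retrain_grid=(1, 5, 10, 50, 100),
    )


def run_full_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "rankings").mkdir(exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)

    # --- data -------------------------------------------------------------
    stage("data")
    truth = None
    if config.matrix_path:
        data = read_expression(config.matrix_path, config.labels_path)
    else:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        if "n_samples_per_class" in syn:
            syn["n_samples_per_class"] = tuple(syn["n_samples_per_class"])
        if "baseline_mean_log_range" in syn:
            syn["baseline_mean_log_range"] = tuple(syn["baseline_mean_log_range"])
        data, truth = generate_counts(SyntheticConfig(**syn))
    done("data")

    # --- preprocess --------------------------------------------------------
    stage("preprocess")
    processed = prepare(
        data,
        train_fraction=config.train_fraction,
        seed=config.seed,
        low_count_threshold=config.low_count_threshold,
        low_count_sample_fraction=config.low_count_sample_fraction,
        pseudocount=config.pseudocount,
    )
    done("preprocess")

    # --- training ----------------------------------------------------------
    stage("train")
    models: dict[str, list] = {}
    acc_rows = []
    for family in config.model_families:
        seeds = [0] if family == "gbt" else list(config.replicate_seeds)
        kwargs = dict(config.model_kwargs.get(family, {}))
        models[family] = []
        for s in seeds:
            model = train_model(processed, family, seed=s,
                                edge_budget=config.edge_budget, **kwargs)
            models[family].append(model)
            acc_rows.append({
                "model_family": family,
                "seed": s,
                "balanced_accuracy_train": balanced_accuracy(
                    model.predict(processed.x_train), processed.y_train),
                "balanced_accuracy_test": balanced_accuracy(
                    model.predict(processed.x_test), processed.y_test),
            })
    pd.DataFrame(acc_rows).to_csv(outdir / "accuracies.csv", index=False)
    done("train")

    # --- rankings ----------------------------------------------------------
    stage("rank")
    x_tr, y_tr = processed.x_train, processed.y_train
    names = processed.kept_gene_names
    rankings: dict[str, list] = {}
    rankings["var"] = [rank_variance(x_tr, names)]
    rankings["pca"] = [rank_pca(x_tr, names)]
    rankings["mi"] = [rank_mutual_information(x_tr, y_tr, names, seed=config.seed)]
    de_ranking, de_stats = rank_differential_expression(x_tr, y_tr, names)
    rankings["de"] = [de_ranking]
    if "gbt" in models:
        rankings["gbt_gain"] = [rank_gbt_gain(models["gbt"][0])]
    for family in ("lr_l1", "lr_l2"):
        if family in models:
            rankings[f"{family}_weight"] = [rank_lr_weights(m) for m in models[family]]
    baseline = default_baseline(processed)
    ig_results: dict[str, list] = {}
    for family in config.model_families:
        if family not in GRADIENT_FAMILIES:
            continue
        reps = []
        for model in models[family]:
            ranking, _ = compute_ig_ranking(
                model, processed, n_steps=config.ig_steps, baseline=baseline,
                max_samples_per_class=config.pg_max_samples, seed=config.seed,
            )
            reps.append(ranking)
        rankings[f"ig_{family}"] = reps
        ig_results[family] = reps
    for method, reps in rankings.items():
        for i, r in enumerate(reps):
            write_ranking(r, outdir / "rankings" / f"{method}_rep{i}.tsv")
    done("rank")

    # --- experiment 0 ------------------------------------------------------
    stage("experiment0")
    exp0_rows = []
    for family, reps in ig_results.items():
        res = run_experiment_0(
            models[family], reps, processed, baseline,
            max_samples=config.pg_max_samples, seed=config.seed, stride=config.pg_stride,
        )
        exp0_rows.append({
            "model_family": family,
            "pgi_mean": res.pgi_mean, "pgi_std": res.pgi_std,
            "pgu_mean": res.pgu_mean, "pgu_std": res.pgu_std,
            "maskable_percent": res.maskable_percent,
        })
    pd.DataFrame(exp0_rows).to_csv(outdir / "experiment0.csv", index=False)
    done("experiment0")

    # --- experiments 1 & 2 + random control --------------------------------
    stage("retrain")
    source = (f"ig_{config.retrain_family}"
              if config.retrain_family in GRADIENT_FAMILIES else "gbt_gain")
    source_rankings = rankings.get(source) or rankings["de"]
    grid = list(config.retrain_grid) if config.retrain_grid else None
    curves = []
    for selection in ("top", "bottom", "random"):
        curve = run_experiment_1_2(
            processed, source_rankings, config.retrain_family,
            grid=grid, selection=selection,
            seeds=list(config.replicate_seeds)[: len(source_rankings)],
            edge_budget=config.edge_budget,
            **config.model_kwargs.get(config.retrain_family, {}),
        )
        for g, m, s in zip(curve.gene_count_grid, curve.balanced_accuracy_mean,
                           curve.balanced_accuracy_std):
            curves.append({
                "selection": selection, "n_genes": int(g),
                "balanced_accuracy_mean": m, "balanced_accuracy_std": s,
                "model_family": config.retrain_family, "ranking": source,
            })
    pd.DataFrame(curves).to_csv(outdir / "retrain_curves.csv", index=False)
    done("retrain")

    # --- overlaps ----------------------------------------------------------
    stage("overlap")
    k_large = min(100, processed.n_genes)
    k_small = min(10, processed.n_genes)
    ov = overlap_matrix(rankings, k_small=k_small, k_large=k_large)
    pd.DataFrame(ov.combined(), index=ov.methods, columns=ov.methods).to_csv(
        outdir / "overlap.csv")
    done("overlap")

    # --- t-statistic diagnostic --------------------------------------------
    stage("diagnostics")
    diag_rows = []
    for method, reps in rankings.items():
        if method == "de":
            continue
        try:
            d = tstat_correlation(reps[0], de_stats, names, seed=config.seed)
        except ValueError:
            continue
        diag_rows.append({"method": method, **d})
    pd.DataFrame(diag_rows).to_csv(outdir / "tstat_diagnostics.csv", index=False)
    done("diagnostics")

    # --- ORA ----------------------------------------------------------------
    stage("ora")
    if config.gmt_path:
        collection = read_gmt(config.gmt_path)
    elif truth is not None and truth.all_de_indices():
        collection = generate_toy_gmt(
            truth, n_decoy_sets=config.ora_decoy_sets, seed=config.seed,
            n_genes=data.n_genes,
        )
    else:
        collection = None
    if collection is not None:
        # one ranking per method (replicate 1 for ML-based methods)
        first = {m: reps[0] for m, reps in rankings.items()}
        result = ora_report(first, collection, set(names),
                            top_n=config.ora_top_n, q_threshold=config.ora_q_threshold)
        ora_rows = []
        for method, sig in result.per_method.items():
            for rank_i, e in enumerate(sig[:10], start=1):
                ora_rows.append({
                    "method": method, "display_rank": rank_i, "set_name": e.set_name,
                    "overlap": e.overlap_count, "set_size": e.set_size,
                    "raw_p": e.raw_p, "q_value": e.q_value,
                    "flagged_by": ";".join(e.flagged_by),
                })
        pd.DataFrame(ora_rows).to_csv(outdir / "ora.tsv", sep="\t", index=False)
    done("ora")

    manifest = {
        "package_version": gxplain.__version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seeds": list(config.replicate_seeds),
        "n_samples": data.n_samples,
        "n_genes_raw": data.n_genes,
        "n_genes_kept": processed.n_genes,
        "stage_seconds": timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
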