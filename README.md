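# gxplain

Comparative gene-expression profiling: how much should you trust the gene
rankings that classifiers and explainability methods produce?

Supervised models — logistic regression (L1/L2), shallow multilayer
perceptrons, graph convolutional networks on gene co-expression graphs, and
gradient-boosted trees — can classify phenotypes (e.g. tumour vs healthy
tissue, cancer subtypes) from bulk RNA-seq expression with high balanced
accuracy. Each model also implies a gene importance ranking: filter
statistics (variance, PCA loadings, mutual information, differential
expression), embedded scores (regression weights, tree gains), and post-hoc
attributions (integrated gradients). `gxplain` trains all of these on a
common preprocessed matrix and evaluates the rankings with prediction-gap
masking, retraining experiments, top-k overlap statistics, and
over-representation analysis — on synthetic count data with planted ground
truth, or on your own count matrices.

It is written for computational biologists and ML researchers who want a
tested, deterministic harness for asking: are the top-ranked genes
sufficient? Are the bottom-ranked genes really uninformative? Do different
methods agree?

## The core quantities

**Integrated gradients (IG).** For a trained classifier `f`, target class
`c`, sample `x` and baseline `x′` (mean of normal-class training samples for
binary tasks, mean of all training samples otherwise):

    φ_g(x) = (x_g − x′_g) ∫₀¹ ∂f_c/∂x_g |_{x′ + α(x − x′)} dα

approximated by a midpoint Riemann sum. Attributions satisfy completeness:
`Σ_g φ_g(x) = f_c(x) − f_c(x′)` up to integration error. Local scores from
correctly classified training samples are aggregated per class,

    φ_g^class = (1/N_c) Σ_n |φ_g(xⁿ)| / ‖φ(xⁿ)‖ ,

and averaged over classes into a global per-gene score.

**Prediction gaps.** Genes are masked progressively (replaced by the
baseline value) in ranking order, and

    PG = (1/G) Σ_{m=1..G} max(f_c(x) − f_c(x̃_m), 0) / f_c(x) .

Masking most-important-first gives **PGI**, least-important-first gives
**PGU**. For a faithful ranking PGI is large (important genes collapse the
prediction quickly) and PGU is small — PGU estimates the fraction of genes
the model actually needs.

**Rankings.** Per-gene variance (1/N convention), |loading| on the first
principal component, kNN-estimated mutual information I(X_g; Y), a Welch
unequal-variance t-test score −log10(BH-adjusted p) (minimum over class
pairs for C > 2; externally computed DESeq2/edgeR tables can be imported via
the ranking TSV format), |W_g| (or the mean over classes of |W_cg|) for
logistic models, and total split gain for boosted trees.

**Evaluation.** Retraining experiments measure held-out balanced accuracy
(mean per-class recall) of models retrained on the g highest-, lowest-, or
randomly-ranked genes; overlap matrices report the percentage of shared
genes among method top-10/top-100 lists averaged over replicate pairs; ORA
scores top-gene lists against GMT gene-set collections with the exact
hypergeometric upper tail and Benjamini–Hochberg control.

**Synthetic data.** Negative-binomial counts (variance μ + φμ²) with
uniform log2 baseline means, planted per-class fold changes, and redundant
gene blocks correlated through a shared log-scale Gaussian factor whose
loading is solved from the target pairwise count correlation. The planted
truth (DE genes, block membership) makes every downstream claim scoreable.

## Worked example

```python
import numpy as np
from gxplain.simulate import SyntheticConfig, generate_counts
from gxplain.preprocess import prepare
from gxplain.experiments import train_model, run_experiment_0
from gxplain.models import balanced_accuracy
from gxplain.attributions import compute_ig_ranking, default_baseline

cfg = SyntheticConfig(
    n_samples_per_class=(100, 100), n_genes=1000,
    n_de_genes_per_class=20, log2_fold_change=2.0, seed=0,
)
data, truth = generate_counts(cfg)
processed = prepare(data, seed=0)      # filter -> log2 CPM -> 60/40 split -> z-score
print(f"kept {processed.n_genes} of {data.n_genes} genes after filtering")

model = train_model(processed, "mlp", seed=0)
acc = balanced_accuracy(model.predict(processed.x_test), processed.y_test)
print(f"MLP balanced accuracy (test): {acc:.3f}")

ig, _ = compute_ig_ranking(model, processed, n_steps=64, max_samples_per_class=10)
planted = {data.gene_names[i] for i in truth.all_de_indices()}
print(f"planted DE genes in IG top-40: {len(set(ig.top(40)) & planted)}/40")

res = run_experiment_0([model], [ig], processed, default_baseline(processed),
                       max_samples=10)
print(f"PGI = {res.pgi_mean:.3f}, PGU = {res.pgu_mean:.3f}")
```

Output:

```
kept 817 of 1000 genes after filtering
MLP balanced accuracy (test): 1.000
planted DE genes in IG top-40: 39/40
PGI = 0.290, PGU = 0.008
```

The MLP classifies the held-out split perfectly; the IG ranking recovers 39
of the 40 planted differentially expressed genes; the small PGU (0.8% of
genes) says the model's decision survives masking almost all low-ranked
genes, while the large PGI says masking the top-ranked genes disturbs it
quickly — the ranking is faithful to the model.

The same workflow is scriptable end to end:

```bash
gxplain all --seed 0 --out runs/demo      # or: gxplain all --config run.yaml
gxplain simulate --seed 1 --out-matrix counts.tsv --out-labels labels.tsv
gxplain rank --matrix counts.tsv --labels labels.tsv --method de --out de.tsv
```

`gxplain all` writes `accuracies.csv`, per-method ranking TSVs,
`experiment0.csv` (PGI/PGU), `retrain_curves.csv`, `overlap.csv`,
`tstat_diagnostics.csv`, `ora.tsv` and a `manifest.json` with the config
hash and seeds; reruns with the same config are bit-identical.

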