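import numpy as np
import pytest

from gxplain.preprocess import prepare
from gxplain.simulate import SyntheticConfig, generate_counts


@pytest.fixture(scope="session")
def separable_data():
    """Two well-separated classes, 200 genes, 60 samples/class."""
    cfg = SyntheticConfig(
        n_samples_per_class=(60, 60),
        n_genes=200,
        n_de_genes_per_class=10,
        log2_fold_change=3.0,
        baseline_mean_log_range=(2.0, 8.0),
        seed=11,
    )
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def processed(separable_data):
    data, _ = separable_data
    return prepare(data, seed=0)


@pytest.fixture(scope="session")
def lr_model(processed):
    from gxplain.models import train_logistic

    return train_logistic(
        processed.x_train, processed.y_train, processed.kept_gene_names, penalty="l2", seed=0
    )


@pytest.fixture(scope="session")
def mlp_model(processed):
    from gxplain.models import train_mlp

    return train_mlp(
        processed.x_train, processed.y_train, processed.kept_gene_names,
        hidden_sizes=(16,), seed=0,
    )


@pytest.fixture(scope="session")
def gnn_model(processed):
    from gxplain.models import build_correlation_graph, train_gnn

    graph = build_correlation_graph(processed.x_train, max(1, processed.n_genes // 4))
    return train_gnn(
        processed.x_train, processed.y_train, processed.kept_gene_names, graph, seed=0
    )


@pytest.fixture()
def single_informative_gene():
    """20 standardized genes; only gene 0 carries the class signal."""
    rng = np.random.default_rng(7)
    n, g = 200, 20
    x = rng.normal(0, 1, (n, g))
    y = rng.choice([1, 2], size=n)
    x[:, 0] = np.where(y == 2, 2.0, -2.0) + rng.normal(0, 0.3, n)
    names = [f"G{i + 1:06d}" for i in range(g)]
    return x, y, names
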