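"""Co-expression graph construction, coarsening, and a graph convolutional net.

The graph connects co-expressed genes: pairwise Pearson correlations on the
training samples, keeping the ``edge_budget`` edges of largest magnitude
with weight ``|r|`` (the symmetric-normalized propagation assumes
nonnegative weights).  Coarsening is greedy heavy-edge matching: repeatedly
merge the unmatched pair joined by the heaviest edge, summing edge weights
of merged nodes; features are max-pooled over merged pairs.

The network applies the propagation rule ``D^-1/2 (A + I) D^-1/2 X W`` per
convolution layer (shared weights across genes), pools over the recorded
merge pairs after each layer, and finishes with a logistic head on the
flattened node features.  Backpropagation is explicit, so input gradients
(for integrated gradients) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from gxplain.models import _nn
from gxplain.models.base import TrainedModel

DEFAULT_SCHEDULE = [(0, 0.01), (8, 0.001), (14, 1e-4)]


@dataclass
class CorrelationGraph:
    """Symmetric nonnegative gene adjacency with its coarsening history."""

    adjacency: sparse.csr_matrix
    edge_budget: int
    coarsening_maps: list[np.ndarray] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def normalized_propagator(self) -> sparse.csr_matrix:
        """``D^-1/2 (A + I) D^-1/2`` with D the degree matrix of A + I."""
        a_tilde = (self.adjacency + sparse.identity(self.n_nodes, format="csr")).tocsr()
        deg = np.asarray(a_tilde.sum(axis=1)).ravel()
        d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
        return (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()


def build_correlation_graph(train_matrix: np.ndarray, edge_budget: int) -> CorrelationGraph:
    """Keep the ``edge_budget`` gene pairs of largest |Pearson r|.

    Constant gene columns have undefined correlations, treated as 0.
    """
    if edge_budget < 1:
        raise ValueError("edge_budget must be >= 1")
    x = np.asarray(train_matrix, dtype=float)
    g = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    weights = np.abs(corr)
    iu, ju = np.triu_indices(g, k=1)
    vals = weights[iu, ju]
    budget = min(edge_budget, vals.size)
    keep = np.argpartition(-vals, budget - 1)[:budget] if budget < vals.size else np.arange(vals.size)
    rows, cols, data = iu[keep], ju[keep], vals[keep]
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(g, g))
    adj = (adj + adj.T).tocsr()
    return CorrelationGraph(adjacency=adj, edge_budget=edge_budget)


def coarsen_graph(graph: CorrelationGraph) -> CorrelationGraph:
    """One level of greedy heavy-edge matching.

    Returns a new graph whose nodes are the merged pairs plus unmatched
    singletons; merged edge weights are sums of constituent weights
    (within-pair edges vanish into the node).  The node->cluster merge map
    is appended to ``coarsening_maps`` for feature pooling.
    """
    g = graph.n_nodes
    if g < 2:
        raise ValueError("coarsening needs >= 2 nodes")
    coo = sparse.triu(graph.adjacency, k=1).tocoo()
    order = np.argsort(-coo.data, kind="stable")
    matched = np.full(g, -1, dtype=int)
    cluster_of = np.full(g, -1, dtype=int)
    next_cluster = 0
    for e in order:
        i, j = int(coo.row[e]), int(coo.col[e])
        if matched[i] == -1 and matched[j] == -1:
            matched[i] = j
            matched[j] = i
            cluster_of[i] = cluster_of[j] = next_cluster
            next_cluster += 1
    for i in range(g):
        if cluster_of[i] == -1:
            cluster_of[i] = next_cluster
            next_cluster += 1
    k = next_cluster
    p = sparse.coo_matrix((np.ones(g), (cluster_of, np.arange(g))), shape=(k, g)).tocsr()
    merged = (p @ graph.adjacency @ p.T).tocsr()
    merged.setdiag(0.0)
    merged.eliminate_zeros()
    return CorrelationGraph(
        adjacency=merged,
        edge_budget=graph.edge_budget,
        coarsening_maps=[*graph.coarsening_maps, cluster_of],
    )


def _pool_pairs(cluster_of: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster (first, second) node indices; singletons repeat the node."""
    k = int(cluster_of.max()) + 1
    idx_a = np.full(k, -1, dtype=int)
    idx_b = np.full(k, -1, dtype=int)
    for node, cl in enumerate(cluster_of):
        if idx_a[cl] == -1:
            idx_a[cl] = node
        else:
            idx_b[cl] = node
    singleton = idx_b == -1
    idx_b[singleton] = idx_a[singleton]
    return idx_a, idx_b


def _sparse_apply(s: sparse.csr_matrix, h: np.ndarray) -> np.ndarray:
    """Apply (G, G) sparse S to (N, G, F) node features."""
    n, g, f = h.shape
    out = s @ h.transpose(1, 0, 2).reshape(g, n * f)
    return out.reshape(g, n, f).transpose(1, 0, 2)


class _GraphConv:
    """ReLU(b + S H W) with shared (F_in, F_out) weights across nodes."""

    def __init__(self, s: sparse.csr_matrix, f_in: int, f_out: int, rng: np.random.Generator):
        self.s = s
        scale = np.sqrt(2.0 / f_in)
        self.params = {"w": rng.standard_normal((f_in, f_out)) * scale, "b": np.zeros(f_out)}
        self.grads = {"w": np.zeros_like(self.params["w"]), "b": np.zeros_like(self.params["b"])}

    def forward(self, h: np.ndarray, train: bool) -> np.ndarray:
        self._sh = _sparse_apply(self.s, h)
        z = self._sh @ self.params["w"] + self.params["b"]
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad_z = grad_out * self._mask
        n, g, f_out = grad_z.shape
        f_in = self.params["w"].shape[0]
        self.grads["w"] = self._sh.reshape(-1, f_in).T @ grad_z.reshape(-1, f_out)
        self.grads["b"] = grad_z.sum(axis=(0, 1))
        grad_sh = grad_z @ self.params["w"].T
        return _sparse_apply(self.s, grad_sh)  # S is symmetric


class _PairMaxPool:
    """Max-pool node features over heavy-edge-matching pairs."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, cluster_of: np.ndarray):
        self.idx_a, self.idx_b = _pool_pairs(cluster_of)
        self.n_in = len(cluster_of)

    def forward(self, h: np.ndarray, train: bool) -> np.ndarray:
        ha, hb = h[:, self.idx_a, :], h[:, self.idx_b, :]
        self._take_a = ha >= hb
        return np.where(self._take_a, ha, hb)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, k, f = grad_out.shape
        grad_h = np.zeros((n, self.n_in, f))
        choose = np.where(self._take_a, self.idx_a[None, :, None], self.idx_b[None, :, None])
        s_idx = np.arange(n)[:, None, None]
        f_idx = np.arange(f)[None, None, :]
        np.add.at(grad_h, (s_idx, choose, f_idx), grad_out)
        return grad_h


class GNNModel(TrainedModel):
    def __init__(self, convs, pools, head, gene_names, n_classes, seed, graph):
        self.convs = convs
        self.pools = pools
        self.head = head  # _nn.Dense on flattened node features
        self.model_family = "gnn"
        self.gene_names = list(gene_names)
        self.n_classes = n_classes
        self.replicate_seed = seed
        self.graph = graph

    @property
    def weights(self) -> np.ndarray:
        return self.convs[0].params["w"]

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x[:, :, None]
        for conv, pool in zip(self.convs, self.pools):
            h = conv.forward(h, train)
            h = pool.forward(h, train)
        self._flat_shape = h.shape
        return self.head.forward(h.reshape(h.shape[0], -1), train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return _nn.softmax(self._forward(x, train=False))

    def _backward_input(self, grad_logits: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad_logits).reshape(self._flat_shape)
        for conv, pool in zip(reversed(self.convs), reversed(self.pools)):
            grad = pool.backward(grad)
            grad = conv.backward(grad)
        return grad[:, :, 0]

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        probs = _nn.softmax(self._forward(x, train=False))
        c = target_class - 1
        grad = -probs[:, [c]] * probs
        grad[:, c] += probs[:, c]
        return self._backward_input(grad)


def train_gnn(
    x_train: np.ndarray,
    y_train: np.ndarray,
    gene_names: list[str],
    graph: CorrelationGraph,
    n_conv_layers: int = 1,
    channels: tuple[int, ...] = (8,),
    epochs: int = 15,
    batch_size: int = 32,
    learning_rate_schedule: list[tuple[int, float]] | None = None,
    weight_decay: float = 1e-4,
    seed: int = 0,
) -> GNNModel:
    """Train the graph convolutional classifier on standardized data."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    n, g = x_train.shape
    if graph.n_nodes != g:
        raise ValueError(f"graph has {graph.n_nodes} nodes but data has {g} genes")
    if n_conv_layers not in (1, 2) or len(channels) != n_conv_layers:
        raise ValueError("n_conv_layers must be 1 or 2 with matching channels tuple")
    if n_conv_layers == 2 and g < 2:
        raise ValueError("two conv layers need >= 2 genes")
    schedule = learning_rate_schedule or DEFAULT_SCHEDULE
    n_classes = int(y_train.max())
    y_index = y_train - 1

    rng = np.random.default_rng(seed)
    convs, pools = [], []
    level_graph = graph
    f_in = 1
    for layer_i in range(n_conv_layers):
        s = level_graph.normalized_propagator()
        convs.append(_GraphConv(s, f_in, channels[layer_i], rng))
        coarse = coarsen_graph(level_graph)
        pools.append(_PairMaxPool(coarse.coarsening_maps[-1]))
        level_graph = coarse
        f_in = channels[layer_i]
    head = _nn.Dense(level_graph.n_nodes * f_in, n_classes, rng)
    model = GNNModel(convs, pools, head, gene_names, n_classes, seed, graph)

    all_layers = [*convs, head]
    opt = _nn.Adam(all_layers, lr=schedule[0][1], weight_decay=weight_decay)
    for epoch in range(epochs):
        opt.lr = _nn.lr_at(epoch, schedule)
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = perm[start:start + batch_size]
            logits = model._forward(x_train[batch], train=True)
            probs = _nn.softmax(logits)
            loss, grad = _nn.cross_entropy_grad(probs, y_index[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(f"GNN loss diverged at epoch {epoch}")
            model._backward_input(grad)
            opt.step()
    return model
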