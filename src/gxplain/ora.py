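"""Over-representation analysis of top-ranked genes against gene sets.

For a gene list of size ``n`` drawn from a universe of ``M`` genes, the
overlap ``k`` with a gene set of size ``K`` (intersected with the universe)
is scored with the hypergeometric upper tail ``P(X >= k)`` — enrichment
only, one-sided.  p-values are Benjamini-Hochberg adjusted across all sets
of the collection, filtered at a q-value threshold, and the top sets per
method are cross-flagged when they also appear among another method's
top-100 significant sets.

The universe is the post-filter gene list of the analysed dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gxplain.datasets import GeneSetCollection
from gxplain.rankers import GeneRanking


@dataclass
class SetEnrichment:
    set_name: str
    overlap_count: int
    set_size: int
    list_size: int
    universe_size: int
    raw_p: float
    q_value: float
    flagged_by: list[str]


@dataclass
class ORAResult:
    """Per-method enrichment tables and Fig.-style display sets."""

    per_method: dict[str, list[SetEnrichment]]   # significant sets, sorted
    top10: dict[str, list[str]]                  # display set names
    list_sizes: dict[str, int]


def hypergeometric_enrichment(
    top_genes: set[str],
    gene_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Overlap count and exact upper-tail p-value P(X >= k).

    ``gene_set`` is intersected with the universe before testing;
    ``top_genes`` must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not top_genes <= universe:
        raise ValueError("top genes must be a subset of the universe")
    m = len(universe)
    kk = len(gene_set & universe)
    n = len(top_genes)
    k = len(top_genes & gene_set & universe)
    # survival function at k-1 is the exact tail sum P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, m, kk, n))
    return k, min(max(p, 0.0), 1.0)


def ora_report(
    rankings: dict[str, GeneRanking],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    top_n: int = 100,
    q_threshold: float = 0.05,
    flag_top: int = 100,
) -> ORAResult:
    """Run ORA for each method's top genes and cross-flag shared sets.

    A method whose ranking has fewer than ``top_n`` nonzero scores uses all
    its nonzero-score genes instead.  An empty significant list is a valid
    outcome, not an error.
    """
    universe = set(universe)
    per_method: dict[str, list[SetEnrichment]] = {}
    list_sizes: dict[str, int] = {}
    set_names = collection.names()
    for method, ranking in rankings.items():
        if set(ranking.gene_names) != universe:
            raise ValueError(f"ranking {method!r} does not match the universe")
        n_use = min(top_n, ranking.n_nonzero) if ranking.n_nonzero else top_n
        top = set(ranking.top(n_use))
        list_sizes[method] = n_use
        rows = []
        for name in set_names:
            genes = set(collection.genes(name))
            k, p = hypergeometric_enrichment(top, genes, universe)
            rows.append((name, k, len(genes & universe), p))
        raw_p = np.array([r[3] for r in rows])
        _, q, _, _ = multipletests(raw_p, method="fdr_bh")
        entries = [
            SetEnrichment(
                set_name=name,
                overlap_count=k,
                set_size=kk,
                list_size=n_use,
                universe_size=len(universe),
                raw_p=p,
                q_value=float(qv),
                flagged_by=[],
            )
            for (name, k, kk, p), qv in zip(rows, q)
        ]
        significant = [e for e in entries if e.q_value <= q_threshold]
        significant.sort(key=lambda e: (e.q_value, e.raw_p, e.set_name))
        per_method[method] = significant

    top10 = {m: [e.set_name for e in sig[:10]] for m, sig in per_method.items()}
    for method, sig in per_method.items():
        for entry in sig[:10]:
            for other, other_sig in per_method.items():
                if other == method:
                    continue
                other_top100 = {e.set_name for e in other_sig[:flag_top]}
                if entry.set_name in other_top100:
                    entry.flagged_by.append(other)
    return ORAResult(per_method=per_method, top10=top10, list_sizes=list_sizes)
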