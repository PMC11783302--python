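"""Core containers and readers/writers for the standard file formats.

An :class:`ExpressionDataset` holds a raw (or normalized) samples x genes
expression matrix with unique gene names, unique sample ids and integer class
labels in ``1..C``.  Gene-set collections follow the MSigDB GMT dialect.
Rankings are exchanged as three-column TSV (gene_name, score, rank), which is
also the import path for externally computed differential-expression rankings
(e.g. DESeq2 / edgeR tables converted to ``-log10(adjusted p)`` scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file: readers reject rather than silently coerce."""


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample class labels.

    Parameters
    ----------
    counts
        ``(N, G)`` nonnegative matrix. Raw integer counts after simulation or
        loading; real-valued after CPM/log2 normalization.
    gene_names
        ``G`` unique gene identifiers.
    sample_ids
        ``N`` unique sample identifiers.
    labels
        ``N`` integer class labels in ``1..C``; every class has >= 1 sample.
    """

    counts: np.ndarray
    gene_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, g = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if self.labels.shape != (n,):
            raise ValueError("labels must be one integer per sample")
        dup = _duplicates(self.gene_names)
        if dup:
            raise FormatError(f"duplicate gene names: {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise FormatError(f"duplicate sample ids: {sorted(dup)[:5]}")
        c = int(self.labels.max(initial=0))
        present = set(np.unique(self.labels).tolist())
        if self.labels.size and (self.labels.min() < 1 or present != set(range(1, c + 1))):
            raise ValueError(f"labels must cover 1..C with no gaps, got classes {sorted(present)}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep)
        return replace(
            self,
            counts=self.counts[:, keep],
            gene_names=[self.gene_names[i] for i in keep],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_names == other.gene_names
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.counts, other.counts)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, [gene, ...])``."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            dup = _duplicates(genes)
            if dup:
                raise FormatError(f"duplicate genes {sorted(dup)} in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    transpose: bool = False,
) -> ExpressionDataset:
    """Read an expression matrix plus a two-column labels table.

    The matrix is samples-in-rows, genes-in-columns with the first column
    holding sample ids (use ``transpose=True`` for genes-in-rows dumps).  The
    labels file has columns ``sample_id`` and ``label``.  Samples present in
    the matrix but absent from the labels table are an error.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    if transpose:
        df = df.T
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    if non_numeric.isna().values.sum() > df.isna().values.sum():
        mask = non_numeric.isna() & ~df.isna()
        r, c = np.argwhere(mask.values)[0]
        raise FormatError(
            f"non-numeric cell at sample {df.index[r]!r}, gene {df.columns[c]!r} in {matrix_path}"
        )
    lab = pd.read_csv(labels_path, sep=_sep_for(labels_path), index_col=0)
    lab_map = lab.iloc[:, 0]
    missing = [s for s in df.index if s not in lab_map.index]
    if missing:
        raise FormatError(f"samples missing from labels file: {missing[:5]}")
    labels = lab_map.loc[df.index].astype(int).to_numpy()
    return ExpressionDataset(
        counts=non_numeric.to_numpy(dtype=float),
        gene_names=[str(g) for g in df.columns],
        sample_ids=[str(s) for s in df.index],
        labels=labels,
    )


def write_expression(data: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path) -> None:
    """Write matrix TSV/CSV (samples in rows) and a sample_id/label table."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    pd.DataFrame(data.counts, index=data.sample_ids, columns=data.gene_names).to_csv(
        matrix_path, sep=_sep_for(matrix_path), index_label="sample_id"
    )
    pd.DataFrame({"label": data.labels}, index=data.sample_ids).to_csv(
        labels_path, sep=_sep_for(labels_path), index_label="sample_id"
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (name, description, genes...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("GMT set %r line %d: dropped duplicate gene names", name, lineno)
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


_RANKING_HEADER = "# ties broken by gene-name lexicographic order; higher score = more important"


def write_ranking(ranking, path: str | Path) -> None:
    """Write a ranking TSV (gene_name, score, rank; rank 1 = most important)."""
    scores = np.asarray(ranking.scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    with open(path, "w") as fh:
        fh.write(_RANKING_HEADER + f"\n# method: {ranking.method_name}\n")
        fh.write("gene_name\tscore\trank\n")
        for g, s, r in zip(ranking.gene_names, scores, ranking.ranks):
            fh.write(f"{g}\t{s:.12g}\t{r}\n")


def read_ranking(path: str | Path, method_name: str | None = None):
    """Read a ranking TSV back; exact inverse of :func:`write_ranking`.

    Also the entry point for externally computed DE rankings: a table with a
    ``-log10(adjusted p)`` score column in the same three-column layout.
    """
    from gxplain.rankers import GeneRanking

    method = method_name or "imported"
    genes: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("# method:") and method_name is None:
                    method = line.split(":", 1)[1].strip()
                continue
            if line.startswith("gene_name"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"ranking line has {len(fields)} fields: {line!r}")
            genes.append(fields[0])
            value = float(fields[1])
            if np.isnan(value):
                raise ValueError(f"NaN score for gene {fields[0]!r}")
            scores.append(value)
    return GeneRanking(method_name=method, gene_names=genes, scores=np.array(scores))
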