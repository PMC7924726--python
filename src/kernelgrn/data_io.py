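"""Input/output and gene-universe alignment.

The inference pipeline consumes four kinds of input:

* feature matrices (genes x samples; expression or methylation), TSV/CSV
  with gene identifiers in the first column and sample identifiers in the
  header row;
* an undirected protein--protein interaction (PPI) graph as a 2- or
  3-column edge list (gene_a, gene_b[, weight]);
* known TF->gene regulations, either a genes x TFs matrix of {+1, -1}
  labels or a 3-column gold-standard edge list (tf, target, 1);
* and, on the output side, the genes x TFs decision-score matrix and a
  ranked edge list.

Gene identifier matching is exact-string and case-sensitive.  After
intersection the canonical gene order is sorted lexicographic, so results
do not depend on input file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "GeneGraph",
    "RegulationMatrix",
    "ScoreMatrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_gene_graph",
    "write_gene_graph",
    "read_regulations",
    "write_regulations",
    "align_universe",
    "read_score_matrix",
    "write_score_matrix",
    "write_network",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)
    return ids


@dataclass
class FeatureMatrix:
    """A genes x samples real-valued matrix (expression, methylation, ...)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values after load")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def restrict(self, gene_ids: Sequence[str]) -> "FeatureMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return FeatureMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])


@dataclass
class GeneGraph:
    """Undirected weighted graph on gene identifiers (e.g. a PPI network)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            warnings.warn(f"dropping {len(loops)} self-loop(s) from gene graph")
            g.remove_edges_from(loops)
        for u, v, w in g.edges(data="weight", default=1.0):
            if w < 0:
                raise ValueError(f"negative edge weight on ({u}, {v}): {w}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def adjacency(self, order: Sequence[str]) -> np.ndarray:
        """Dense symmetric adjacency in the given gene order."""
        missing = [g for g in order if g not in self.graph]
        if missing:
            raise KeyError(f"genes absent from graph: {missing[:5]}")
        return nx.to_numpy_array(self.graph, nodelist=list(order), weight="weight")

    def restrict(self, gene_ids: Sequence[str]) -> "GeneGraph":
        # rebuild so the node order follows the requested (canonical) order,
        # keeping isolated genes of the universe as nodes
        keep = set(gene_ids)
        sub = nx.Graph()
        sub.add_nodes_from(gene_ids)
        sub.add_weighted_edges_from(
            (u, v, w)
            for u, v, w in self.graph.edges(data="weight", default=1.0)
            if u in keep and v in keep
        )
        return GeneGraph(sub)


@dataclass
class RegulationMatrix:
    """Genes x TFs label matrix over {+1, -1}.

    ``known_mask`` marks entries backed by prior knowledge (the listed
    gold-standard edges); in unknown-mask mode unlisted entries may carry
    label 0 meaning "unknown", which training still treats as -1.
    """

    gene_ids: list[str]
    tf_ids: list[str]
    labels: np.ndarray
    known_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        shape = (len(self.gene_ids), len(self.tf_ids))
        if self.labels.shape != shape:
            raise ValueError(f"labels shape {self.labels.shape} != {shape}")
        allowed = {-1, 1} if self.known_mask is None else {-1, 0, 1}
        bad = set(np.unique(self.labels)) - allowed
        if bad:
            raise ValueError(f"labels must be in {sorted(allowed)}; found {sorted(bad)}")
        if self.known_mask is not None:
            self.known_mask = np.asarray(self.known_mask, dtype=bool)
            if self.known_mask.shape != shape:
                raise ValueError("known_mask shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def positives_per_tf(self) -> np.ndarray:
        return (self.labels == 1).sum(axis=0)

    def zero_positive_tfs(self) -> list[str]:
        counts = self.positives_per_tf()
        return [tf for tf, c in zip(self.tf_ids, counts) if c == 0]

    def training_labels(self, tf_id: str) -> np.ndarray:
        """+-1 vector for one TF; unknown (0) entries train as -1."""
        j = self.tf_ids.index(tf_id)
        y = self.labels[:, j].astype(float)
        y[y == 0] = -1.0
        return y

    def restrict(self, gene_ids: Sequence[str]) -> "RegulationMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        mask = None if self.known_mask is None else self.known_mask[rows]
        return RegulationMatrix(list(gene_ids), list(self.tf_ids), self.labels[rows], mask)


@dataclass
class ScoreMatrix:
    """Genes x TFs decision scores: the inferred network before ranking.

    ``column_status`` maps each TF to "ok", "skipped" (too few positives)
    or "failed" (worker error); skipped/failed columns hold NaN, never a
    silent zero.
    """

    gene_ids: list[str]
    tf_ids: list[str]
    scores: np.ndarray
    column_status: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise ValueError("scores shape mismatch")
        for tf in self.tf_ids:
            self.column_status.setdefault(tf, "ok")

    def scored_tfs(self) -> list[str]:
        return [tf for tf in self.tf_ids if self.column_status[tf] == "ok"]

    def column(self, tf_id: str) -> np.ndarray:
        return self.scores[:, self.tf_ids.index(tf_id)]


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, dialect: str) -> pd.DataFrame:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_feature_matrix(path, dialect: str = "tsv", missing: str = "reject") -> FeatureMatrix:
    """Read a genes x samples matrix.

    ``missing`` controls rows with missing entries: "reject" drops them
    (with a warning), "impute" replaces them with the row mean, "error"
    raises.
    """
    df = _read_table(path, dialect)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id {dup[0]!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise ValueError(f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}")
        df[col] = coerced
    if df.isna().any().any():
        if missing == "error":
            raise ValueError(f"missing values in {path}")
        if missing == "impute":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        elif missing == "reject":
            n_before = len(df)
            df = df.dropna(axis=0)
            warnings.warn(f"dropped {n_before - len(df)} gene row(s) with missing values")
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    return FeatureMatrix(list(df.index), [str(c) for c in df.columns], df.to_numpy(float))


def write_feature_matrix(fm: FeatureMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    fm.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_gene_graph(path, dialect: str = "tsv", nodes: Sequence[str] | None = None) -> GeneGraph:
    """Read a 2- or 3-column undirected edge list (gene_a, gene_b[, weight]).

    ``nodes`` optionally declares the gene universe the graph lives on, so
    genes without any recorded interaction become isolated nodes instead
    of silently shrinking the universe at alignment.
    """
    sep = "\t" if dialect == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1])
    if len(df) and df.shape[1] not in (2, 3):
        raise ValueError(f"edge list must have 2 or 3 columns, found {df.shape[1]}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    for row in df.itertuples(index=False):
        u, v = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) == 3 else 1.0
        g.add_edge(u, v, weight=w)
    return GeneGraph(g)


def write_gene_graph(gg: GeneGraph, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    with open(path, "w") as fh:
        for u, v, w in sorted(gg.graph.edges(data="weight", default=1.0)):
            fh.write(f"{u}{sep}{v}{sep}{w:g}\n")


def read_regulations(
    path,
    format: str = "edge_list",
    gene_ids: Sequence[str] | None = None,
    tf_ids: Sequence[str] | None = None,
    dialect: str = "tsv",
    allow_unknown: bool = False,
) -> RegulationMatrix:
    """Read known TF->gene regulations.

    ``edge_list``: 3 columns (tf, target, 1); requires a declared gene
    universe ``gene_ids``.  Listed pairs become +1 (and known), everything
    else -1 (or 0/unknown when ``allow_unknown``).

    ``matrix``: genes x TFs of {+1, -1} (0 allowed only with
    ``allow_unknown``, where it means unknown).
    """
    sep = "\t" if dialect == "tsv" else ","
    if format == "matrix":
        df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
        labels = df.to_numpy()
        mask = None
        if allow_unknown:
            mask = labels != 0
        else:
            bad = ~np.isin(labels, (-1, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"label {labels[i, j]!r} at gene {df.index[i]!r}, TF "
                    f"{df.columns[j]!r}: labels must be +1/-1"
                )
        return RegulationMatrix(list(df.index), [str(c) for c in df.columns], labels, mask)
    if format != "edge_list":
        raise ValueError(f"format must be 'matrix' or 'edge_list', got {format!r}")
    if gene_ids is None:
        raise ValueError("edge_list format requires a declared gene universe")
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1, 2])
    if len(df) and df.shape[1] != 3:
        raise ValueError(f"gold-standard edge list must have 3 columns, found {df.shape[1]}")
    edges = [(str(t), str(g), v) for t, g, v in df.itertuples(index=False)] if len(df) else []
    for tf, gene, val in edges:
        if float(val) != 1.0:
            raise ValueError(f"edge ({tf}, {gene}) has indicator {val!r}; expected 1")
    return regulations_from_edges([(t, g) for t, g, _ in edges], gene_ids, tf_ids, allow_unknown)


def regulations_from_edges(
    edges: Iterable[tuple[str, str]],
    gene_ids: Sequence[str],
    tf_ids: Sequence[str] | None = None,
    allow_unknown: bool = False,
) -> RegulationMatrix:
    """Build a RegulationMatrix from (tf, target) pairs over a gene universe."""
    edges = list(edges)
    seen_tfs: list[str] = []
    for tf, _ in edges:
        if tf not in seen_tfs:
            seen_tfs.append(tf)
    if tf_ids is None:
        tf_ids = sorted(seen_tfs)
    else:
        tf_ids = list(tf_ids)
        extra = [tf for tf in seen_tfs if tf not in tf_ids]
        if extra:
            raise ValueError(f"edge list names TFs outside the declared list: {extra[:5]}")
    gene_ids = list(gene_ids)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tidx = {t: j for j, t in enumerate(tf_ids)}
    fill = 0 if allow_unknown else -1
    labels = np.full((len(gene_ids), len(tf_ids)), fill, dtype=np.int8)
    mask = np.zeros_like(labels, dtype=bool)
    for tf, gene in edges:
        if gene not in gidx:
            raise ValueError(f"edge target {gene!r} outside declared gene universe")
        labels[gidx[gene], tidx[tf]] = 1
        mask[gidx[gene], tidx[tf]] = True
    for tf in tf_ids:
        targets = [g for t, g in edges if t == tf]
        if targets and set(targets) == {tf}:
            warnings.warn(f"TF {tf!r} appears as its own sole target")
    return RegulationMatrix(gene_ids, tf_ids, labels, mask if allow_unknown else mask)


def write_regulations(R: RegulationMatrix, path, format: str = "edge_list", dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    if format == "matrix":
        pd.DataFrame(R.labels, index=R.gene_ids, columns=R.tf_ids).to_csv(
            path, sep=sep, index_label="gene"
        )
        return
    if format != "edge_list":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for j, tf in enumerate(R.tf_ids):
            for i, g in enumerate(R.gene_ids):
                if R.labels[i, j] == 1:
                    fh.write(f"{tf}{sep}{g}{sep}1\n")


# ---------------------------------------------------------------------------
# universe alignment


def align_universe(inputs: Mapping[str, object]):
    """Restrict every input to the intersection of gene ids.

    Returns ``(aligned, dropped)`` where ``aligned`` maps the same keys to
    restricted objects sharing one canonical (sorted) gene order and
    ``dropped`` maps each key to the ids it lost.  Raises on an empty
    intersection.
    """
    if not inputs:
        raise ValueError("align_universe needs at least one input")
    universes = {name: set(_gene_ids_of(obj)) for name, obj in inputs.items()}
    common = set.intersection(*universes.values())
    if not common:
        raise ValueError("gene universes have an empty intersection")
    order = sorted(common)
    aligned = {name: obj.restrict(order) for name, obj in inputs.items()}
    dropped = {name: sorted(ids - common) for name, ids in universes.items()}
    return aligned, dropped


def _gene_ids_of(obj) -> list[str]:
    if hasattr(obj, "gene_ids"):
        return obj.gene_ids
    raise TypeError(f"cannot extract gene ids from {type(obj).__name__}")


# ---------------------------------------------------------------------------
# score matrix / network output


def write_score_matrix(ds: ScoreMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    pd.DataFrame(ds.scores, index=ds.gene_ids, columns=ds.tf_ids).to_csv(
        path, sep=sep, index_label="gene"
    )


def read_score_matrix(path, dialect: str = "tsv") -> ScoreMatrix:
    df = _read_table(path, dialect)
    scores = df.to_numpy(float)
    status = {
        str(tf): ("skipped" if np.isnan(scores[:, j]).all() else "ok")
        for j, tf in enumerate(df.columns)
    }
    return ScoreMatrix(list(df.index), [str(c) for c in df.columns], scores, status)


def write_network(
    ds: ScoreMatrix,
    path,
    top_k: int | None = None,
    known: RegulationMatrix | None = None,
    known_policy: str = "mark",
    dialect: str = "tsv",
) -> pd.DataFrame:
    """Write the ranked TF->gene edge list.

    Rows are (tf, gene, score) sorted by descending score, ties broken by
    (tf, gene) lexicographic.  Skipped/failed columns are omitted.  Genes
    that were training positives for a TF (per ``known``) are excluded or
    marked according to ``known_policy`` ("exclude" | "mark" | "keep").
    """
    if top_k is not None and top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    if known_policy not in ("exclude", "mark", "keep"):
        raise ValueError(f"unknown known_policy {known_policy!r}")
    rows = []
    known_set: set[tuple[str, str]] = set()
    if known is not None:
        for j, tf in enumerate(known.tf_ids):
            for i, g in enumerate(known.gene_ids):
                if known.labels[i, j] == 1:
                    known_set.add((tf, g))
    for tf in ds.scored_tfs():
        col = ds.column(tf)
        for gene, score in zip(ds.gene_ids, col):
            is_known = (tf, gene) in known_set
            if is_known and known_policy == "exclude":
                continue
            rows.append((tf, gene, float(score), int(is_known)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if top_k is not None:
        rows = rows[:top_k]
    cols = ["tf", "gene", "score"]
    if known is not None and known_policy == "mark":
        df = pd.DataFrame(rows, columns=cols + ["known"])
    else:
        df = pd.DataFrame([r[:3] for r in rows], columns=cols)
    sep = "\t" if dialect == "tsv" else ","
    df.to_csv(path, sep=sep, index=False)
    return df
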