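"""Gene-cluster interaction graphs built from shared samples.

Nodes are extreme sample clusters of individual genes; an undirected edge
connects two clusters of *different* genes whenever their member-sample
sets intersect in at least ``min_shared`` samples.  Shared membership —
rather than curated interactions — is what links genes here, so the
graph reflects which genes partition the cohort the same way.

Per-sample classification units are induced subgraphs: for one sample,
all clusters containing it plus the edges among them.  Held-out samples
(whose clusters were built on training data only) are routed to the
nearest cluster median per gene, within a radius of one training
standard deviation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .cluster import CandidateCluster

__all__ = [
    "ExpressionGraph",
    "SampleSubgraph",
    "build_expression_graph",
    "extract_sample_subgraph",
    "assign_heldout_sample",
    "SubgraphScaler",
    "normalize_graph_features",
    "export_graph",
    "import_graph",
    "graphs_equal",
]


@dataclass
class ExpressionGraph:
    """Undirected graph over selected CandidateClusters of many genes.

    ``node_names`` are stable strings ``"<gene>|<dendrogram node>"``;
    edges are stored once with ``u_idx < v_idx``.
    """

    clusters: list[CandidateCluster]
    node_names: list[str]
    sample_ids: list[str]
    edges_u: np.ndarray
    edges_v: np.ndarray
    shared_counts: np.ndarray
    min_shared: int

    @property
    def n_nodes(self) -> int:
        return len(self.clusters)

    @property
    def n_edges(self) -> int:
        return int(self.edges_u.size)

    def gene_of(self, idx: int) -> str:
        return self.clusters[idx].gene_id

    def genes(self) -> list[str]:
        return sorted({c.gene_id for c in self.clusters})

    def clusters_by_gene(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.clusters):
            out.setdefault(c.gene_id, []).append(i)
        return out

    def edge_list(self) -> list[tuple[int, int, int]]:
        return [
            (int(u), int(v), int(s))
            for u, v, s in zip(self.edges_u, self.edges_v, self.shared_counts)
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(min_shared=self.min_shared,
                     sample_ids=",".join(self.sample_ids))
        for name, c in zip(self.node_names, self.clusters):
            g.add_node(
                name,
                gene_id=c.gene_id,
                median_value=float(c.median_value),
                size=int(c.size),
                tree_level=int(c.tree_level),
                extremeness=float(c.extremeness if c.extremeness is not None else 0.0),
                members=",".join(sorted(c.members)),
            )
        for u, v, s in self.edge_list():
            cu, cv = self.clusters[u], self.clusters[v]
            g.add_edge(self.node_names[u], self.node_names[v],
                       shared_count=int(s),
                       level_u=int(cu.tree_level), level_v=int(cv.tree_level))
        return g


def build_expression_graph(selected: dict[str, list[CandidateCluster]],
                           min_shared: int = 1) -> ExpressionGraph:
    """Connect clusters of different genes that share >= ``min_shared`` samples.

    Intersection counts are computed through a boolean membership matrix
    product, then same-gene pairs and sub-threshold pairs are dropped.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be at least 1")
    clusters: list[CandidateCluster] = []
    genes: list[str] = []
    for gene in sorted(selected):
        for c in sorted(selected[gene], key=lambda c: c.key):
            clusters.append(c)
            genes.append(gene)
    sample_ids = sorted({s for c in clusters for s in c.members})
    n, m = len(clusters), len(sample_ids)
    names = [f"{c.gene_id}|{c.node_id}" for c in clusters]
    if len(set(names)) != n:  # node_id collisions can only come from caller misuse
        names = [f"{c.gene_id}|{i}" for i, c in enumerate(clusters)]

    if n == 0:
        return ExpressionGraph(clusters, names, sample_ids,
                               np.empty(0, int), np.empty(0, int),
                               np.empty(0, int), min_shared)

    col = {s: j for j, s in enumerate(sample_ids)}
    member = np.zeros((n, m), dtype=np.float32)
    for i, c in enumerate(clusters):
        member[i, [col[s] for s in c.members]] = 1.0
    inter = member @ member.T  # shared sample counts, exact small integers

    gene_arr = np.array(genes)
    same_gene = gene_arr[:, None] == gene_arr[None, :]
    iu, iv = np.triu_indices(n, k=1)
    counts = inter[iu, iv]
    keep = (counts >= min_shared) & ~same_gene[iu, iv]
    return ExpressionGraph(
        clusters=clusters,
        node_names=names,
        sample_ids=sample_ids,
        edges_u=iu[keep].astype(int),
        edges_v=iv[keep].astype(int),
        shared_counts=counts[keep].astype(int),
        min_shared=min_shared,
    )


# -- sample-specific subgraphs -------------------------------------------------

NODE_FEATURES_ALL = ["median_value", "size", "tree_level", "expression"]
NODE_FEATURES_GENE = ["expression"]


@dataclass
class SampleSubgraph:
    """Induced subgraph of one sample: the unit of graph-level classification."""

    sample_id: str
    node_names: list[str]
    gene_ids: list[str]
    node_features: np.ndarray
    feature_names: list[str]
    edge_index: np.ndarray  # (2, E) with u < v, undirected stored once
    edge_weights: np.ndarray
    label: str | None = None
    is_empty: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def adjacency(self, weighted: bool = True) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.edge_index.size:
            u, v = self.edge_index
            w = self.edge_weights if weighted else np.ones_like(self.edge_weights)
            a[u, v] = w
            a[v, u] = w
        return a


def _node_feature_row(c: CandidateCluster, expr: float | None,
                      feature_mode: str) -> list[float]:
    if feature_mode == "gene":
        return [0.0 if expr is None else float(expr)]
    row = [float(c.median_value), float(c.size), float(c.tree_level)]
    row.append(0.0 if expr is None else float(expr))
    return row


def extract_sample_subgraph(
    g: ExpressionGraph,
    sample_id: str,
    feature_mode: str = "all",
    expression: dict[str, float] | None = None,
    label: str | None = None,
    membership: dict[str, int] | None = None,
) -> SampleSubgraph:
    """Induce the subgraph of clusters containing ``sample_id``.

    ``expression`` maps gene id -> the sample's normalized value (used as
    a node feature).  For held-out samples pass ``membership`` (gene ->
    node index) from :func:`assign_heldout_sample` instead of relying on
    member sets.
    """
    if feature_mode not in ("gene", "all"):
        raise ValueError("feature_mode must be 'gene' or 'all'")
    if membership is not None:
        node_idx = sorted(membership.values())
    else:
        node_idx = [i for i, c in enumerate(g.clusters) if sample_id in c.members]
    feature_names = NODE_FEATURES_GENE if feature_mode == "gene" else NODE_FEATURES_ALL

    if not node_idx:
        warnings.warn(f"sample {sample_id!r} belongs to no cluster; empty subgraph")
        return SampleSubgraph(
            sample_id=sample_id, node_names=[], gene_ids=[],
            node_features=np.zeros((0, len(feature_names))),
            feature_names=list(feature_names),
            edge_index=np.zeros((2, 0), dtype=int),
            edge_weights=np.zeros(0), label=label, is_empty=True,
        )

    pos = {n: k for k, n in enumerate(node_idx)}
    rows = []
    for i in node_idx:
        c = g.clusters[i]
        expr = None if expression is None else expression.get(c.gene_id)
        rows.append(_node_feature_row(c, expr, feature_mode))
    keep = [(pos[u], pos[v], s) for u, v, s in g.edge_list()
            if u in pos and v in pos]
    if keep:
        eu, ev, ew = (np.array(x) for x in zip(*keep))
    else:
        eu = ev = np.zeros(0, dtype=int)
        ew = np.zeros(0)
    return SampleSubgraph(
        sample_id=sample_id,
        node_names=[g.node_names[i] for i in node_idx],
        gene_ids=[g.clusters[i].gene_id for i in node_idx],
        node_features=np.asarray(rows, dtype=float),
        feature_names=list(feature_names),
        edge_index=np.vstack([eu, ev]).astype(int),
        edge_weights=ew.astype(float),
        label=label,
        is_empty=False,
    )


def assign_heldout_sample(
    g: ExpressionGraph,
    sample_expression: dict[str, float],
    assignment_radius: dict[str, float],
) -> dict[str, int]:
    """Route an unseen sample to the nearest cluster median per gene.

    For each gene, the cluster whose median is closest to the sample's
    normalized value wins, provided the absolute difference does not
    exceed that gene's radius (conventionally one training standard
    deviation); otherwise the gene contributes no node.
    """
    out: dict[str, int] = {}
    for gene, idxs in g.clusters_by_gene().items():
        if gene not in sample_expression:
            continue
        x = sample_expression[gene]
        radius = assignment_radius.get(gene, np.inf)
        best: tuple[float, tuple[str, ...], int] | None = None
        for i in idxs:
            c = g.clusters[i]
            diff = abs(c.median_value - x)
            cand = (diff, c.key, i)
            if diff <= radius and (best is None or cand < best):
                best = cand
        if best is not None:
            out[gene] = best[2]
    return out


class SubgraphScaler:
    """Min-max feature normalization fit on training subgraphs only.

    Node features and edge weights are scaled to [0, 1] using training
    statistics; out-of-range values from held-out samples are clipped so
    model inputs stay bounded.  Constant features map to 0.
    """

    def fit(self, subgraphs: list[SampleSubgraph]) -> "SubgraphScaler":
        mats = [s.node_features for s in subgraphs if s.n_nodes]
        if not mats:
            raise ValueError("training set has no non-empty subgraphs")
        stacked = np.vstack(mats)
        self.feature_min_ = stacked.min(axis=0)
        self.feature_max_ = stacked.max(axis=0)
        weights = np.concatenate(
            [s.edge_weights for s in subgraphs if s.edge_weights.size]
            or [np.zeros(1)]
        )
        self.weight_min_ = float(weights.min())
        self.weight_max_ = float(weights.max())
        return self

    def _scale(self, x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (x - lo) / span
        out = np.where(np.broadcast_to(span == 0, out.shape), 0.0, out)
        return np.clip(out, 0.0, 1.0)

    def transform(self, subgraphs: list[SampleSubgraph]) -> list[SampleSubgraph]:
        out = []
        for s in subgraphs:
            feats = self._scale(s.node_features, self.feature_min_, self.feature_max_)
            w = self._scale(s.edge_weights, np.array(self.weight_min_),
                            np.array(self.weight_max_))
            out.append(SampleSubgraph(
                sample_id=s.sample_id, node_names=list(s.node_names),
                gene_ids=list(s.gene_ids), node_features=feats,
                feature_names=list(s.feature_names),
                edge_index=s.edge_index.copy(), edge_weights=w,
                label=s.label, is_empty=s.is_empty,
            ))
        return out


def normalize_graph_features(subgraphs: list[SampleSubgraph],
                             fit_on: list[str]) -> list[SampleSubgraph]:
    """Scale all subgraphs with statistics from the ``fit_on`` sample ids."""
    train = [s for s in subgraphs if s.sample_id in set(fit_on)]
    scaler = SubgraphScaler().fit(train)
    return scaler.transform(subgraphs)


# -- export / import -----------------------------------------------------------


def graphs_equal(a: ExpressionGraph, b: ExpressionGraph) -> bool:
    """Structural equality: same nodes (with properties) and same edges."""
    def node_map(g: ExpressionGraph) -> dict[str, tuple]:
        return {
            n: (c.gene_id, c.members, round(c.median_value, 9), c.size,
                c.tree_level, round(c.extremeness or 0.0, 9))
            for n, c in zip(g.node_names, g.clusters)
        }

    def edge_map(g: ExpressionGraph) -> dict[frozenset, int]:
        return {
            frozenset((g.node_names[u], g.node_names[v])): s
            for u, v, s in g.edge_list()
        }

    return (a.min_shared == b.min_shared
            and sorted(a.sample_ids) == sorted(b.sample_ids)
            and node_map(a) == node_map(b)
            and edge_map(a) == edge_map(b))


def export_graph(g: ExpressionGraph, path: str | Path,
                 format: str = "graphml") -> list[Path]:
    """Write the graph as GraphML or a nodes.csv + edges.csv pair.

    The CSV pair is laid out for bulk graph-database import; both formats
    round-trip through :func:`import_graph` exactly.
    """
    path = Path(path)
    try:
        if format == "graphml":
            path.parent.mkdir(parents=True, exist_ok=True)
            nx.write_graphml(g.to_networkx(), path)
            return [path]
        if format == "csv_pair":
            path.mkdir(parents=True, exist_ok=True)
            nodes_p, edges_p = path / "nodes.csv", path / "edges.csv"
            with open(nodes_p, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["name", "gene_id", "median_value", "size",
                            "tree_level", "extremeness", "members"])
                for name, c in zip(g.node_names, g.clusters):
                    w.writerow([name, c.gene_id, repr(float(c.median_value)),
                                c.size, c.tree_level,
                                repr(float(c.extremeness or 0.0)),
                                ";".join(sorted(c.members))])
            with open(edges_p, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["source", "target", "shared_count",
                            "level_u", "level_v"])
                for u, v, s in g.edge_list():
                    w.writerow([g.node_names[u], g.node_names[v], s,
                                g.clusters[u].tree_level, g.clusters[v].tree_level])
            (path / "meta.csv").write_text(
                f"min_shared,{g.min_shared}\nsamples,{';'.join(g.sample_ids)}\n")
            return [nodes_p, edges_p, path / "meta.csv"]
        raise ValueError("format must be 'graphml' or 'csv_pair'")
    except OSError as exc:
        raise OSError(f"failed writing graph to {path}: {exc}") from exc


def import_graph(path: str | Path, format: str = "graphml") -> ExpressionGraph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    clusters: list[CandidateCluster] = []
    names: list[str] = []
    edges: list[tuple[str, str, int]] = []
    if format == "graphml":
        g = nx.read_graphml(path)
        min_shared = int(g.graph.get("min_shared", 1))
        sample_ids = [s for s in str(g.graph.get("sample_ids", "")).split(",") if s]
        for name, attrs in sorted(g.nodes(data=True)):
            members = frozenset(attrs["members"].split(","))
            clusters.append(CandidateCluster(
                gene_id=attrs["gene_id"], members=members,
                median_value=float(attrs["median_value"]),
                size=int(attrs["size"]), tree_level=int(attrs["tree_level"]),
                extremeness=float(attrs["extremeness"]),
                node_id=int(str(name).rsplit("|", 1)[1]),
            ))
            names.append(str(name))
        for u, v, attrs in g.edges(data=True):
            edges.append((str(u), str(v), int(attrs["shared_count"])))
    elif format == "csv_pair":
        meta = dict(line.split(",", 1)
                    for line in (path / "meta.csv").read_text().splitlines())
        min_shared = int(meta["min_shared"])
        sample_ids = [s for s in meta["samples"].split(";") if s]
        with open(path / "nodes.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                clusters.append(CandidateCluster(
                    gene_id=row["gene_id"],
                    members=frozenset(row["members"].split(";")),
                    median_value=float(row["median_value"]),
                    size=int(row["size"]), tree_level=int(row["tree_level"]),
                    extremeness=float(row["extremeness"]),
                    node_id=int(row["name"].rsplit("|", 1)[1]),
                ))
                names.append(row["name"])
        with open(path / "edges.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append((row["source"], row["target"],
                              int(row["shared_count"])))
    else:
        raise ValueError("format must be 'graphml' or 'csv_pair'")

    order = sorted(range(len(names)), key=lambda i: names[i])
    clusters = [clusters[i] for i in order]
    names = [names[i] for i in order]
    pos = {n: i for i, n in enumerate(names)}
    tri = sorted(
        (min(pos[u], pos[v]), max(pos[u], pos[v]), s) for u, v, s in edges
    )
    eu = np.array([t[0] for t in tri], dtype=int)
    ev = np.array([t[1] for t in tri], dtype=int)
    ec = np.array([t[2] for t in tri], dtype=int)
    return ExpressionGraph(clusters=clusters, node_names=names,
                           sample_ids=sample_ids, edges_u=eu, edges_v=ev,
                           shared_counts=ec, min_shared=min_shared)
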