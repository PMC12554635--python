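"""Graph-based biomarker selection.

A gene appears in the expression graph as several alternative sample
clusters, which makes raw centrality scores double-count within-gene
structure.  The selection procedure therefore repeatedly samples a
*simple* graph — exactly one cluster per gene, chosen uniformly — and
accumulates three per-gene scores across iterations:

* degree: the gene's edge count in the sampled graph;
* community frequency: how many other genes share the gene's Louvain
  community (community size minus one);
* pathway: how many gene sets enriched in the gene's community
  (hypergeometric test, BH < 0.05) contain the gene.

Score distributions are zero-inflated (a gene is often isolated), so
significance is assessed by a resampling bootstrap against the pooled
score distribution, and genes are ranked per criterion by BH-adjusted
p-value; the final markers are those with the smallest rank sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import cluster_gene
from .datasets import ExpressionDataset
from .graph import ExpressionGraph, build_expression_graph
from .preprocess import normalize_for_clustering

__all__ = [
    "SimpleGraph",
    "MarkerTable",
    "sample_simple_graph",
    "detect_communities",
    "accumulate_scores",
    "bootstrap_marker_test",
    "adjust_and_rank",
    "read_gmt",
    "GraphMarkerSelector",
]

CRITERIA = ("degree", "freq", "pathway")


@dataclass
class SimpleGraph:
    """One sampled cluster-node per gene, with the induced parent edges."""

    genes: list[str]
    chosen: dict[str, int]  # gene -> node index in the parent graph
    edges: list[tuple[str, str, int]]  # (gene_u, gene_v, shared_count)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(self.edges, weight="shared_count")
        return g


class _GraphIndex:
    """Vectorized view of an ExpressionGraph for fast repeated sampling."""

    def __init__(self, g: ExpressionGraph):
        by_gene = g.clusters_by_gene()
        self.genes = sorted(by_gene)
        gene_pos = {x: i for i, x in enumerate(self.genes)}
        self.n_genes = len(self.genes)
        self.cluster_counts = np.array([len(by_gene[x]) for x in self.genes])
        # within-gene position of every node
        self.node_gene = np.empty(g.n_nodes, dtype=int)
        self.node_slot = np.empty(g.n_nodes, dtype=int)
        self.slots = {x: np.array(by_gene[x]) for x in self.genes}
        for x in self.genes:
            for slot, node in enumerate(by_gene[x]):
                self.node_gene[node] = gene_pos[x]
                self.node_slot[node] = slot
        self.eu_gene = self.node_gene[g.edges_u]
        self.ev_gene = self.node_gene[g.edges_v]
        self.eu_slot = self.node_slot[g.edges_u]
        self.ev_slot = self.node_slot[g.edges_v]
        self.shared = np.asarray(g.shared_counts)

    def sample(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Pick one cluster slot per gene; return (picks, active edge mask)."""
        picks = (rng.random(self.n_genes) * self.cluster_counts).astype(int)
        active = (picks[self.eu_gene] == self.eu_slot) & \
                 (picks[self.ev_gene] == self.ev_slot)
        return picks, active

    def degrees(self, active: np.ndarray) -> np.ndarray:
        return (np.bincount(self.eu_gene[active], minlength=self.n_genes)
                + np.bincount(self.ev_gene[active], minlength=self.n_genes))


def sample_simple_graph(g: ExpressionGraph,
                        rng: np.random.Generator | int = 0) -> SimpleGraph:
    """Uniformly pick one cluster per gene and keep the induced edges."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    idx = _GraphIndex(g)
    picks, active = idx.sample(rng)
    chosen = {gene: int(idx.slots[gene][picks[i]])
              for i, gene in enumerate(idx.genes)}
    edges = [(idx.genes[idx.eu_gene[e]], idx.genes[idx.ev_gene[e]],
              int(idx.shared[e]))
             for e in np.flatnonzero(active)]
    return SimpleGraph(genes=list(idx.genes), chosen=chosen, edges=edges)


def detect_communities(sg: SimpleGraph | nx.Graph,
                       seed: int = 0) -> list[set[str]]:
    """Louvain modularity communities; isolated nodes become singletons."""
    g = sg.to_networkx() if isinstance(sg, SimpleGraph) else sg
    if g.number_of_nodes() == 0:
        return []
    return [set(c) for c in nx.community.louvain_communities(g, seed=seed)]


def _pathway_scores_for_partition(
    communities: list[set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> dict[str, int]:
    """Per gene: number of BH-enriched gene sets (within its community) containing it."""
    n_universe = len(universe)
    scores: dict[str, int] = {g: 0 for g in universe}
    set_names = sorted(gene_sets)
    set_members = {s: gene_sets[s] & universe for s in set_names}
    for comm in communities:
        if len(comm) < 2:
            continue
        pvals = []
        for s in set_names:
            members = set_members[s]
            k = len(comm & members)
            pvals.append(stats.hypergeom.sf(k - 1, n_universe,
                                            len(members), len(comm)))
        reject = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
        for s, rej in zip(set_names, reject):
            if rej:
                for gene in comm & set_members[s]:
                    scores[gene] += 1
    return scores


@dataclass
class MarkerTable:
    """Accumulated per-gene scores, bootstrap p-values, ranks and selection."""

    genes: list[str]
    scores: dict[str, np.ndarray]  # criterion -> (n_genes, n_iterations)
    p_values: dict[str, np.ndarray] = field(default_factory=dict)
    p_adjusted: dict[str, np.ndarray] = field(default_factory=dict)
    ranks: dict[str, np.ndarray] = field(default_factory=dict)
    rank_sum: np.ndarray | None = None
    selected: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return next(iter(self.scores.values())).shape[1]

    def criteria(self) -> list[str]:
        return [c for c in CRITERIA if c in self.scores]

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray | list] = {"gene_id": self.genes}
        for c in self.criteria():
            data[f"mean_{c}"] = self.scores[c].mean(axis=1)
            if c in self.p_values:
                data[f"p_{c}"] = self.p_values[c]
            if c in self.p_adjusted:
                data[f"padj_{c}"] = self.p_adjusted[c]
            if c in self.ranks:
                data[f"rank_{c}"] = self.ranks[c]
        if self.rank_sum is not None:
            data["rank_sum"] = self.rank_sum
        data["selected"] = [g in set(self.selected) for g in self.genes]
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def accumulate_scores(
    g: ExpressionGraph,
    gene_sets: dict[str, set[str]] | None = None,
    n_iterations: int = 10000,
    seed: int = 0,
    community_seed: int = 0,
    compute: tuple[str, ...] | None = None,
) -> MarkerTable:
    """Run the graph-sampling loop and accumulate per-gene score lists.

    ``compute`` restricts the criteria (e.g. ``("degree",)`` for speed);
    by default degree and community frequency are always computed and the
    pathway criterion only when ``gene_sets`` is given.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    idx = _GraphIndex(g)
    if compute is None:
        compute = ("degree", "freq") + (("pathway",) if gene_sets else ())
    unknown = set(compute) - set(CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    if "pathway" in compute and not gene_sets:
        raise ValueError("pathway criterion requires gene_sets")

    rng = np.random.default_rng(seed)
    universe = set(idx.genes)
    gene_pos = {x: i for i, x in enumerate(idx.genes)}
    out = {c: np.zeros((idx.n_genes, n_iterations)) for c in compute}
    need_comm = "freq" in compute or "pathway" in compute

    for t in range(n_iterations):
        picks, active = idx.sample(rng)
        if "degree" in compute:
            out["degree"][:, t] = idx.degrees(active)
        if need_comm:
            gnx = nx.Graph()
            gnx.add_nodes_from(range(idx.n_genes))
            eidx = np.flatnonzero(active)
            gnx.add_edges_from(zip(idx.eu_gene[eidx], idx.ev_gene[eidx]))
            comms = nx.community.louvain_communities(gnx, seed=community_seed)
            if "freq" in compute:
                for comm in comms:
                    for gi in comm:
                        out["freq"][gi, t] = len(comm) - 1
            if "pathway" in compute:
                named = [{idx.genes[i] for i in comm} for comm in comms]
                ps = _pathway_scores_for_partition(named, gene_sets, universe)
                for gene, s in ps.items():
                    out["pathway"][gene_pos[gene], t] = s
    return MarkerTable(genes=list(idx.genes), scores=out)


def bootstrap_marker_test(table: MarkerTable, n_boot: int = 1000,
                          seed: int = 0) -> MarkerTable:
    """Bootstrap p-values per criterion under gene exchangeability.

    Observed statistic for gene g: mean of g's scores minus the mean of
    all other genes' pooled scores.  A gene's scores are strongly
    correlated across sampling iterations (its expected degree is fixed
    by its cluster structure), so the null must resample at the gene
    level: each bootstrap replicate redraws the iteration indices with
    replacement and substitutes the scores of a uniformly chosen *other*
    gene.  The one-sided p-value carries a +1/(n_boot+1) continuity
    correction so p is never exactly 0.
    """
    rng = np.random.default_rng(seed)
    n_genes = len(table.genes)
    for crit in table.criteria():
        s = table.scores[crit]
        n_iter = s.shape[1]
        if np.all(s == 0):
            table.p_values[crit] = np.ones(n_genes)
            table.degenerate.append(crit)
            warnings.warn(f"criterion {crit!r} is identically zero; p set to 1")
            continue
        gene_means = s.mean(axis=1)
        # per-replicate iteration resample, shared across genes; row_means[j, b]
        # is gene j's mean score over the b-th resampled iteration set
        row_means = np.empty((n_genes, n_boot))
        for b in range(n_boot):
            idx = rng.integers(0, n_iter, size=n_iter)
            row_means[:, b] = s[:, idx].mean(axis=1)
        # uniform draw over the n_genes - 1 *other* genes, shared then shifted
        u = rng.integers(0, n_genes - 1, size=n_boot)
        p = np.empty(n_genes)
        cols = np.arange(n_boot)
        for g in range(n_genes):
            others = u + (u >= g)
            null = row_means[others, cols]
            p[g] = (1.0 + np.count_nonzero(null >= gene_means[g])) \
                / (n_boot + 1.0)
        table.p_values[crit] = p
    return table


def adjust_and_rank(table: MarkerTable,
                    criteria: tuple[str, ...] | None = None,
                    top_k: int = 20) -> MarkerTable:
    """BH-adjust, rank per criterion, and select the smallest rank sums."""
    if criteria is None:
        criteria = tuple(c for c in table.criteria() if c in table.p_values)
    missing = [c for c in criteria if c not in table.p_values]
    if missing:
        raise ValueError(f"criteria without p-values: {missing}")
    n_genes = len(table.genes)
    if top_k > n_genes:
        warnings.warn("top_k exceeds gene count; selecting all genes")
        top_k = n_genes

    rank_sum = np.zeros(n_genes)
    for crit in criteria:
        adj = multipletests(table.p_values[crit], method="fdr_bh")[1]
        table.p_adjusted[crit] = adj
        r = stats.rankdata(adj, method="average")
        table.ranks[crit] = r
        rank_sum += r
    table.rank_sum = rank_sum

    best_p = np.min(np.column_stack([table.p_values[c] for c in criteria]), axis=1)
    order = sorted(range(n_genes),
                   key=lambda i: (rank_sum[i], best_p[i], table.genes[i]))
    table.selected = [table.genes[i] for i in order[:top_k]]
    return table


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT: one set per line — name, description, then gene ids."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        out[parts[0]] = {g for g in parts[2:] if g}
    return out


class GraphMarkerSelector:
    """End-to-end marker selection as a sklearn-style transformer.

    ``fit`` normalizes the expression data for the chosen design
    (per-class z-scores for unpaired, bounded class ratios for paired),
    clusters each gene in one dimension, assembles the shared-sample
    graph, and runs the sampling / bootstrap / rank-sum procedure.

    Attributes (after fit): ``graph_``, ``marker_table_``,
    ``selected_genes_``.
    """

    def __init__(self, design: str = "unpaired", min_size: int = 2,
                 fraction: float = 0.1, min_shared: int = 1,
                 n_iterations: int = 10000, n_boot: int = 1000,
                 top_k: int = 20, gene_sets: dict[str, set[str]] | None = None,
                 criteria: tuple[str, ...] | None = None,
                 random_state: int = 0):
        self.design = design
        self.min_size = min_size
        self.fraction = fraction
        self.min_shared = min_shared
        self.n_iterations = n_iterations
        self.n_boot = n_boot
        self.top_k = top_k
        self.gene_sets = gene_sets
        self.criteria = criteria
        self.random_state = random_state

    _param_names = ("design", "min_size", "fraction", "min_shared",
                    "n_iterations", "n_boot", "top_k", "gene_sets",
                    "criteria", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "GraphMarkerSelector":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: ExpressionDataset,
            genes: list[str] | None = None) -> "GraphMarkerSelector":
        genes = genes if genes is not None else list(data.gene_ids)
        norm = normalize_for_clustering(data, self.design)
        gene_rows = {g: i for i, g in enumerate(norm.gene_ids)}
        selected: dict[str, list] = {}
        for gene in genes:
            clusters = cluster_gene(norm.values[gene_rows[gene]], norm.columns,
                                    gene, min_size=self.min_size,
                                    fraction=self.fraction)
            if clusters:
                selected[gene] = clusters
        self.graph_ = build_expression_graph(selected, min_shared=self.min_shared)
        table = accumulate_scores(
            self.graph_, gene_sets=self.gene_sets,
            n_iterations=self.n_iterations, seed=self.random_state,
            community_seed=self.random_state,
        )
        table = bootstrap_marker_test(table, n_boot=self.n_boot,
                                      seed=self.random_state + 1)
        table = adjust_and_rank(table, criteria=self.criteria, top_k=self.top_k)
        self.marker_table_ = table
        self.selected_genes_ = list(table.selected)
        return self

    def get_support(self) -> list[str]:
        return list(self.selected_genes_)

    def transform(self, data: ExpressionDataset) -> pd.DataFrame:
        return data.to_frame().loc[self.selected_genes_]

    def fit_transform(self, data: ExpressionDataset,
                      genes: list[str] | None = None) -> pd.DataFrame:
        return self.fit(data, genes=genes).transform(data)
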