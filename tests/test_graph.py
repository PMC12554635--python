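import itertools

import numpy as np
import pytest

from conftest import make_cluster, random_cluster_collection
from exprnet.graph import (SubgraphScaler, assign_heldout_sample,
                           build_expression_graph, export_graph,
                           extract_sample_subgraph, graphs_equal,
                           import_graph, normalize_graph_features)


def brute_force_edges(selected, min_shared):
    """All-pairs intersection oracle over the flattened cluster list."""
    flat = [(g, c) for g in sorted(selected)
            for c in sorted(selected[g], key=lambda c: c.key)]
    edges = set()
    for (ga, ca), (gb, cb) in itertools.combinations(flat, 2):
        if ga == gb:
            continue
        shared = len(ca.members & cb.members)
        if shared >= min_shared:
            edges.add(frozenset([(ga, ca.key), (gb, cb.key)]))
    return edges


class TestBuildGraph:
    def test_single_shared_sample(self, toy_clusters):
        g = build_expression_graph(toy_clusters, min_shared=1)
        assert g.n_nodes == 3
        assert g.n_edges == 1  # gA{s1,s2} ~ gB{s2,s3}
        u, v, s = g.edge_list()[0]
        assert s == 1
        assert {g.gene_of(u), g.gene_of(v)} == {"gA", "gB"}

    def test_threshold_removes_edges(self, toy_clusters):
        g = build_expression_graph(toy_clusters, min_shared=2)
        assert g.n_edges == 0

    def test_min_shared_validation(self, toy_clusters):
        with pytest.raises(ValueError):
            build_expression_graph(toy_clusters, min_shared=0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for rep in range(100):
            selected = random_cluster_collection(rng)
            min_shared = int(rng.integers(1, 4))
            g = build_expression_graph(selected, min_shared=min_shared)
            got = {
                frozenset([(g.gene_of(u), g.clusters[u].key),
                           (g.gene_of(v), g.clusters[v].key)])
                for u, v, _ in g.edge_list()
            }
            assert got == brute_force_edges(selected, min_shared)

    def test_edge_count_monotone_in_min_shared(self):
        rng = np.random.default_rng(1)
        for rep in range(20):
            selected = random_cluster_collection(rng, n_genes=6)
            counts = [build_expression_graph(selected, min_shared=k).n_edges
                      for k in range(1, 6)]
            assert counts == sorted(counts, reverse=True)

    def test_no_same_gene_or_self_edges(self):
        rng = np.random.default_rng(2)
        selected = random_cluster_collection(rng, n_genes=5, max_clusters=4)
        g = build_expression_graph(selected)
        for u, v, _ in g.edge_list():
            assert u != v
            assert g.gene_of(u) != g.gene_of(v)

    def test_shared_counts_exact(self):
        rng = np.random.default_rng(3)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected)
        for u, v, s in g.edge_list():
            assert s == len(g.clusters[u].members & g.clusters[v].members)


class TestSubgraphs:
    def test_sample_in_every_cluster_gets_whole_graph(self):
        sel = {
            "gA": [make_cluster("gA", {"x", "a"}, node_id=1)],
            "gB": [make_cluster("gB", {"x", "b"}, node_id=2)],
        }
        g = build_expression_graph(sel)
        sub = extract_sample_subgraph(g, "x")
        assert sub.n_nodes == g.n_nodes
        assert sub.edge_index.shape[1] == g.n_edges

    def test_sample_in_one_cluster(self, toy_clusters):
        g = build_expression_graph(toy_clusters)
        sub = extract_sample_subgraph(g, "s4")
        assert sub.n_nodes == 1
        assert sub.edge_index.shape[1] == 0

    def test_absent_sample_yields_empty_flag(self, toy_clusters):
        g = build_expression_graph(toy_clusters)
        with pytest.warns(UserWarning):
            sub = extract_sample_subgraph(g, "nobody")
        assert sub.is_empty and sub.n_nodes == 0

    def test_induced_edges_match_list_filter_oracle(self):
        rng = np.random.default_rng(4)
        selected = random_cluster_collection(rng, n_genes=7)
        g = build_expression_graph(selected)
        for sample in g.sample_ids:
            sub = extract_sample_subgraph(g, sample)
            names = set(sub.node_names)
            want = [(u, v) for u, v, _ in g.edge_list()
                    if g.node_names[u] in names and g.node_names[v] in names]
            assert sub.edge_index.shape[1] == len(want)

    def test_every_node_covered_by_some_sample(self):
        rng = np.random.default_rng(5)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected)
        covered = set()
        for sample in g.sample_ids:
            sub = extract_sample_subgraph(g, sample)
            covered.update(sub.node_names)
        assert covered == set(g.node_names)

    def test_feature_modes(self, toy_clusters):
        g = build_expression_graph(toy_clusters)
        expr = {"gA": 0.3, "gB": -0.5, "gC": 1.0}
        all_f = extract_sample_subgraph(g, "s2", feature_mode="all",
                                        expression=expr)
        gene_f = extract_sample_subgraph(g, "s2", feature_mode="gene",
                                         expression=expr)
        assert all_f.node_features.shape[1] == 4
        assert gene_f.node_features.shape[1] == 1


class TestHeldoutAssignment:
    def setup_graph(self):
        sel = {
            "gA": [make_cluster("gA", {"a", "b"}, median=-1.0, node_id=1),
                   make_cluster("gA", {"c", "d"}, median=1.0, node_id=2)],
            "gB": [make_cluster("gB", {"a", "c"}, median=0.0, node_id=3)],
        }
        return build_expression_graph(sel)

    def test_exact_median_match(self):
        g = self.setup_graph()
        m = assign_heldout_sample(g, {"gA": 1.0, "gB": 0.0},
                                  {"gA": 0.5, "gB": 0.5})
        assert g.clusters[m["gA"]].median_value == 1.0
        assert "gB" in m

    def test_outside_radius_contributes_no_node(self):
        g = self.setup_graph()
        m = assign_heldout_sample(g, {"gA": 5.0, "gB": 0.0},
                                  {"gA": 0.5, "gB": 0.5})
        assert "gA" not in m and "gB" in m

    def test_training_sample_self_consistency(self):
        """Routing a training sample through assignment lands in clusters
        that actually contain it for >= 90% of its genes."""
        from exprnet.cluster import cluster_gene
        from exprnet.datasets import generate_unpaired
        from exprnet.preprocess import normalize_for_clustering

        ds = generate_unpaired(40, 25, 5, effect_size=2.0, seed=21)
        norm = normalize_for_clustering(ds, "unpaired")
        selected = {}
        for i, gene in enumerate(norm.gene_ids):
            cl = cluster_gene(norm.values[i], norm.columns, gene)
            if cl:
                selected[gene] = cl
        g = build_expression_graph(selected)
        radius = {gene: float(norm.values[i].std(ddof=1))
                  for i, gene in enumerate(norm.gene_ids)}
        rates = []
        for sample in ds.sample_ids[:10]:
            col = norm.columns.index(sample)
            expr = {gene: float(norm.values[i, col])
                    for i, gene in enumerate(norm.gene_ids)}
            membership = assign_heldout_sample(g, expr, radius)
            checked = [gene for gene, node in membership.items()
                       if sample in {s for c in selected[gene]
                                     for s in c.members}]
            if not checked:
                continue
            ok = sum(sample in g.clusters[node].members
                     for gene, node in membership.items()
                     if gene in set(checked))
            rates.append(ok / len(checked))
        assert np.mean(rates) >= 0.9


class TestFeatureScaling:
    def make_subgraph(self, sample, feats, label="class1"):
        from exprnet.graph import SampleSubgraph
        feats = np.asarray(feats, dtype=float)
        return SampleSubgraph(
            sample_id=sample, node_names=[f"n{i}" for i in range(len(feats))],
            gene_ids=["g"] * len(feats), node_features=feats,
            feature_names=[f"f{j}" for j in range(feats.shape[1])],
            edge_index=np.zeros((2, 0), dtype=int), edge_weights=np.zeros(0),
            label=label)

    def test_minmax_midpoint(self):
        train = self.make_subgraph("t", [[2.0], [6.0]])
        test = self.make_subgraph("x", [[4.0]])
        out = normalize_graph_features([train, test], fit_on=["t"])
        assert out[1].node_features[0, 0] == pytest.approx(0.5)

    def test_out_of_range_clipped(self):
        train = self.make_subgraph("t", [[2.0], [6.0]])
        test = self.make_subgraph("x", [[100.0], [-50.0]])
        out = normalize_graph_features([train, test], fit_on=["t"])
        assert np.all(out[1].node_features <= 1.0)
        assert np.all(out[1].node_features >= 0.0)

    def test_refit_idempotent(self):
        rng = np.random.default_rng(0)
        subs = [self.make_subgraph(f"s{i}", rng.normal(size=(4, 3)))
                for i in range(5)]
        scaler = SubgraphScaler().fit(subs)
        once = scaler.transform(subs)
        again = SubgraphScaler().fit(once).transform(once)
        for a, b in zip(once, again):
            assert np.allclose(a.node_features, b.node_features)

    def test_constant_feature_maps_to_zero(self):
        train = self.make_subgraph("t", [[3.0, 1.0], [3.0, 2.0]])
        out = normalize_graph_features([train], fit_on=["t"])
        assert np.allclose(out[0].node_features[:, 0], 0.0)


class TestExport:
    def test_round_trip_both_formats(self, tmp_path):
        rng = np.random.default_rng(6)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected, min_shared=2)
        export_graph(g, tmp_path / "g.graphml", format="graphml")
        back = import_graph(tmp_path / "g.graphml", format="graphml")
        assert graphs_equal(g, back)
        export_graph(g, tmp_path / "csv", format="csv_pair")
        back2 = import_graph(tmp_path / "csv", format="csv_pair")
        assert graphs_equal(g, back2)

    def test_empty_graph_files_valid(self, tmp_path):
        g = build_expression_graph({})
        files = export_graph(g, tmp_path / "empty", format="csv_pair")
        nodes = (tmp_path / "empty" / "nodes.csv").read_text().splitlines()
        assert len(nodes) == 1  # header only
        back = import_graph(tmp_path / "empty", format="csv_pair")
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_file_counts_match_graph(self, tmp_path):
        rng = np.random.default_rng(7)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected)
        export_graph(g, tmp_path / "csv", format="csv_pair")
        n_nodes = len((tmp_path / "csv" / "nodes.csv").read_text()
                      .strip().splitlines()) - 1
        n_edges = len((tmp_path / "csv" / "edges.csv").read_text()
                      .strip().splitlines()) - 1
        assert n_nodes == g.n_nodes and n_edges == g.n_edges
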