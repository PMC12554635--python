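import numpy as np
import pytest

from conftest import make_cluster, random_cluster_collection
from exprnet.graph import build_expression_graph
from exprnet.select import (GraphMarkerSelector, MarkerTable,
                            accumulate_scores, adjust_and_rank,
                            bootstrap_marker_test, detect_communities,
                            read_gmt, sample_simple_graph)


def bh_stepup(pvals):
    """Independent Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestSampling:
    def test_single_cluster_gene_always_chosen(self, toy_clusters):
        g = build_expression_graph(toy_clusters)
        sg = sample_simple_graph(g, rng=0)
        assert set(sg.genes) == {"gA", "gB", "gC"}
        assert len(sg.chosen) == 3

    def test_one_node_per_gene_always(self):
        rng = np.random.default_rng(0)
        selected = random_cluster_collection(rng, n_genes=6)
        g = build_expression_graph(selected)
        for seed in range(20):
            sg = sample_simple_graph(g, rng=seed)
            assert sorted(sg.chosen) == sorted(selected)
            chosen_genes = [g.gene_of(i) for i in sg.chosen.values()]
            assert len(set(chosen_genes)) == len(chosen_genes)

    def test_induced_edges_subset_of_parent(self):
        rng = np.random.default_rng(1)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected)
        parent = {frozenset((g.gene_of(u), g.gene_of(v)))
                  for u, v, _ in g.edge_list()}
        sg = sample_simple_graph(g, rng=3)
        for gu, gv, _ in sg.edges:
            assert frozenset((gu, gv)) in parent


class TestCommunities:
    def test_disconnected_triangles(self):
        sel = {}
        for tri, genes in enumerate((("a", "b", "c"), ("d", "e", "f"))):
            samples = {f"t{tri}_1", f"t{tri}_2"}
            for gene in genes:
                sel[gene] = [make_cluster(gene, samples, node_id=1)]
        g = build_expression_graph(sel)
        sg = sample_simple_graph(g, rng=0)
        comms = detect_communities(sg, seed=0)
        assert sorted(sorted(c) for c in comms) == [["a", "b", "c"],
                                                   ["d", "e", "f"]]

    def test_complete_graph_single_community(self):
        sel = {gene: [make_cluster(gene, {"s1", "s2"}, node_id=1)]
               for gene in ("a", "b", "c", "d")}
        g = build_expression_graph(sel)
        comms = detect_communities(sample_simple_graph(g, rng=0), seed=0)
        assert len(comms) == 1

    def test_modularity_non_negative_vs_trivial(self):
        import networkx as nx
        rng = np.random.default_rng(2)
        selected = random_cluster_collection(rng)
        g = build_expression_graph(selected)
        sg = sample_simple_graph(g, rng=1)
        gnx = sg.to_networkx()
        if gnx.number_of_edges():
            comms = detect_communities(sg, seed=0)
            q = nx.community.modularity(gnx, comms)
            assert q >= 0.0

    def test_isolated_nodes_are_singletons(self):
        sel = {
            "a": [make_cluster("a", {"s1"}, node_id=1)],
            "b": [make_cluster("b", {"s2"}, node_id=1)],
        }
        g = build_expression_graph(sel)
        comms = detect_communities(sample_simple_graph(g, rng=0), seed=0)
        assert sorted(sorted(c) for c in comms) == [["a"], ["b"]]


class TestAccumulate:
    def test_edgeless_graph_all_degrees_zero(self):
        sel = {
            "a": [make_cluster("a", {"s1"}, node_id=1)],
            "b": [make_cluster("b", {"s2"}, node_id=1)],
        }
        g = build_expression_graph(sel)
        t = accumulate_scores(g, n_iterations=20, seed=0)
        assert np.all(t.scores["degree"] == 0)

    def test_pathway_disabled_without_gene_sets(self):
        rng = np.random.default_rng(3)
        g = build_expression_graph(random_cluster_collection(rng))
        t = accumulate_scores(g, n_iterations=10, seed=0)
        assert "pathway" not in t.scores
        assert set(t.scores) == {"degree", "freq"}

    def test_hub_gene_outscores_background(self):
        # one gene shares samples with everyone; others only with the hub
        sel = {"hub": [make_cluster("hub", {f"s{i}" for i in range(10)},
                                    node_id=1)]}
        for k in range(6):
            sel[f"g{k}"] = [make_cluster(f"g{k}", {f"s{k}"}, node_id=1)]
        g = build_expression_graph(sel)
        t = accumulate_scores(g, n_iterations=50, seed=0)
        means = dict(zip(t.genes, t.scores["degree"].mean(axis=1)))
        assert means["hub"] > max(v for k, v in means.items() if k != "hub")

    def test_degree_sum_equals_twice_edges(self):
        rng = np.random.default_rng(4)
        g = build_expression_graph(random_cluster_collection(rng))
        t = accumulate_scores(g, n_iterations=5, seed=7)
        rng2 = np.random.default_rng(7)
        from exprnet.select import _GraphIndex
        idx = _GraphIndex(g)
        for it in range(5):
            _, active = idx.sample(rng2)
            assert t.scores["degree"][:, it].sum() == 2 * active.sum()

    def test_pathway_scores_on_constructed_enrichment(self):
        # genes a,b,c form one tight community and exactly cover set S1
        samples = {"s1", "s2", "s3"}
        sel = {gene: [make_cluster(gene, samples, node_id=1)]
               for gene in ("a", "b", "c")}
        for k in range(5):
            sel[f"bg{k}"] = [make_cluster(f"bg{k}", {f"x{k}"}, node_id=1)]
        g = build_expression_graph(sel)
        gene_sets = {"S1": {"a", "b", "c"}, "S2": {"bg0", "bg1"}}
        t = accumulate_scores(g, gene_sets=gene_sets, n_iterations=5, seed=0)
        means = dict(zip(t.genes, t.scores["pathway"].mean(axis=1)))
        assert means["a"] > 0 and means["b"] > 0 and means["c"] > 0
        assert means["bg0"] == 0

    def test_determinism(self):
        rng = np.random.default_rng(5)
        g = build_expression_graph(random_cluster_collection(rng))
        t1 = accumulate_scores(g, n_iterations=20, seed=9)
        t2 = accumulate_scores(g, n_iterations=20, seed=9)
        for crit in t1.scores:
            assert np.array_equal(t1.scores[crit], t2.scores[crit])


class TestBootstrap:
    def make_table(self, scores):
        scores = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
        genes = [f"g{i}" for i in
                 range(next(iter(scores.values())).shape[0])]
        return MarkerTable(genes=genes, scores=scores)

    def test_extreme_gene_gets_minimal_p(self):
        s = np.zeros((5, 40))
        s[0] = 100.0  # always above the pooled maximum of the others
        t = bootstrap_marker_test(self.make_table({"degree": s}),
                                  n_boot=200, seed=0)
        assert t.p_values["degree"][0] == pytest.approx(1 / 201)

    def test_p_values_in_open_unit_interval(self):
        rng = np.random.default_rng(0)
        s = rng.poisson(3, size=(8, 30)).astype(float)
        t = bootstrap_marker_test(self.make_table({"degree": s}),
                                  n_boot=99, seed=1)
        p = t.p_values["degree"]
        assert np.all(p > 0) and np.all(p <= 1)

    def test_null_gene_p_roughly_uniform(self):
        """A gene exchangeable with the pool has ~uniform p over replicates."""
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(200):
            s = rng.poisson(3, size=(10, 25)).astype(float)
            t = bootstrap_marker_test(self.make_table({"degree": s}),
                                      n_boot=99, seed=rep)
            pvals.append(t.p_values["degree"][0])
        from scipy import stats
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.001

    def test_degenerate_criterion_flagged(self):
        t = bootstrap_marker_test(
            self.make_table({"degree": np.zeros((4, 10))}), n_boot=50, seed=0)
        assert np.all(t.p_values["degree"] == 1.0)
        assert "degree" in t.degenerate


class TestAdjustAndRank:
    def make_table_with_p(self, p_by_crit):
        n = len(next(iter(p_by_crit.values())))
        t = MarkerTable(genes=[f"g{i}" for i in range(n)],
                        scores={c: np.zeros((n, 1)) for c in p_by_crit})
        t.scores = {c: np.zeros((n, 1)) for c in p_by_crit}
        t.p_values = {c: np.asarray(p, dtype=float)
                      for c, p in p_by_crit.items()}
        return t

    def test_single_criterion_reduction(self):
        p = [0.5, 0.01, 0.2, 0.9]
        t = adjust_and_rank(self.make_table_with_p({"degree": p}), top_k=2)
        assert t.selected == ["g1", "g2"]

    def test_dominant_gene_always_selected(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0.1, 1, 10)
        p2 = rng.uniform(0.1, 1, 10)
        p1[4] = p2[4] = 1e-6
        t = adjust_and_rank(
            self.make_table_with_p({"degree": p1, "freq": p2}), top_k=3)
        assert "g4" in t.selected
        assert t.rank_sum[4] == t.rank_sum.min()

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=15)
            t = adjust_and_rank(self.make_table_with_p({"degree": p}),
                                top_k=5)
            assert np.allclose(t.p_adjusted["degree"], bh_stepup(p))

    def test_top_k_overflow_warns(self):
        with pytest.warns(UserWarning):
            t = adjust_and_rank(
                self.make_table_with_p({"degree": [0.1, 0.2]}), top_k=10)
        assert len(t.selected) == 2


class TestGmtAndSelector:
    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\ng2line\tother\tg3\n")
        sets = read_gmt(path)
        assert sets == {"S1": {"g1", "g2"}, "g2line": {"g3"}}
        (tmp_path / "bad.gmt").write_text("onlyname\n")
        with pytest.raises(ValueError):
            read_gmt(tmp_path / "bad.gmt")

    def test_selector_deterministic_and_sklearn_like(self, planted_unpaired):
        kwargs = dict(n_iterations=50, n_boot=50, top_k=5, random_state=3)
        a = GraphMarkerSelector(**kwargs).fit(planted_unpaired)
        b = GraphMarkerSelector(**kwargs).fit(planted_unpaired)
        assert a.selected_genes_ == b.selected_genes_
        assert np.array_equal(a.marker_table_.rank_sum,
                              b.marker_table_.rank_sum)
        params = a.get_params()
        assert params["n_iterations"] == 50
        frame = a.transform(planted_unpaired)
        assert list(frame.index) == a.selected_genes_

    def test_marker_table_tsv(self, tmp_path, planted_unpaired):
        sel = GraphMarkerSelector(n_iterations=20, n_boot=20, top_k=5,
                                  random_state=0).fit(planted_unpaired)
        out = tmp_path / "markers.tsv"
        sel.marker_table_.to_tsv(out)
        import pandas as pd
        frame = pd.read_csv(out, sep="\t")
        assert "rank_sum" in frame.columns
        assert frame["selected"].sum() == 5
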