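"""Interaction-graph construction, clustering, modularity, nulls, and
annotation-connectivity statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from xlmap.errors import DataError, DegenerateInputError
from xlmap.io import AnnotationSet, CrossLink, CrossLinkDataset
from xlmap.network import (
    build_network,
    coannotation_fraction,
    coannotation_statistic,
    components,
    degree_powerlaw_fit,
    girvan_newman_cluster,
    modularity,
    path_distance_statistic,
    rewire_null,
    term_enrichment,
)
from xlmap.synthetic import make_planted_network


class TestBuildNetwork:
    def test_inter_links_aggregate_into_weighted_edge(self):
        ds = CrossLinkDataset([
            CrossLink("A", 1, "B", 2, samples=frozenset({"s1"})),
            CrossLink("A", 3, "B", 4, samples=frozenset({"s2"})),
            CrossLink("A", 5, "A", 9, samples=frozenset({"s1"})),
        ])
        g = build_network(ds)
        assert list(g.edges()) == [("A", "B")]
        assert g["A"]["B"]["weight"] == 2
        assert g["A"]["B"]["sample_count"] == 2

    def test_excluded_accession_removes_edges(self):
        ds = CrossLinkDataset([
            CrossLink("A", 1, "B", 2),
            CrossLink("A", 3, "B", 4),
        ])
        assert build_network(ds, exclude=["A"]).number_of_edges() == 0

    def test_ambiguous_links_excluded_by_default(self):
        ds = CrossLinkDataset([CrossLink("A", 1, "B", 2, ambiguous=True)])
        assert build_network(ds).number_of_edges() == 0
        assert build_network(ds, include_ambiguous=True).number_of_edges() == 1


class TestComponents:
    def test_single_component_is_core(self):
        g = nx.path_graph(5)
        core, side, rest = components(g)
        assert len(core) == 5 and side == [] and rest == set()

    def test_side_modules_and_remainder(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations("abcde", 2))  # 5-clique
        g.add_edges_from([("x", "y"), ("y", "z")])  # 3-path
        g.add_edge("p", "q")  # isolated pair
        core, side, rest = components(g)
        assert core == set("abcde")
        assert [sorted(s) for s in side] == [["x", "y", "z"]]
        assert rest == {"p", "q"}

    def test_tie_broken_by_smallest_member(self):
        g = nx.Graph([("b", "c"), ("a", "d")])
        core, _, _ = components(g, k=2)
        assert core == {"a", "d"}


class TestPowerlawFit:
    def test_exact_power_law_recovered(self):
        # degree histogram f(d) = 16 * d^-2 over degrees {1, 2, 4}
        g = nx.Graph()
        g.add_edges_from(("X", f"Y{i}") for i in range(4))          # X: degree 4
        g.add_edges_from((f"Y{i}", f"L{i}") for i in range(4))      # Y: degree 2
        g.add_edges_from((f"P{i}", f"Q{i}") for i in range(6))      # 12 more leaves
        hist = {}
        for _, d in g.degree():
            hist[d] = hist.get(d, 0) + 1
        assert hist == {1: 16, 2: 4, 4: 1}
        slope, intercept, r2 = degree_powerlaw_fit(g)
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_regular_graph_degenerate(self):
        with pytest.raises(DegenerateInputError):
            degree_powerlaw_fit(nx.cycle_graph(10))

    def test_matches_closed_form_regression(self):
        g, _, _ = make_planted_network(3, 15, 0.4, 0.05, seed=9)
        slope, intercept, r2 = degree_powerlaw_fit(g)
        degrees = [d for _, d in g.degree() if d > 0]
        values, counts = np.unique(degrees, return_counts=True)
        x, y = np.log10(values), np.log10(counts)
        n = len(x)
        sl = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        ic = (y.sum() - sl * x.sum()) / n
        assert slope == pytest.approx(sl, abs=1e-9)
        assert intercept == pytest.approx(ic, abs=1e-9)


class TestModularity:
    def test_single_community_is_zero(self):
        g = nx.karate_club_graph()
        assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_matches_networkx_on_random_partitions(self):
        g, _, _ = make_planted_network(3, 10, 0.5, 0.05, seed=4)
        rng = np.random.default_rng(7)
        for _ in range(10):
            part = {n: int(rng.integers(0, 4)) for n in g.nodes}
            communities = [
                {n for n in g if part[n] == c} for c in set(part.values())
            ]
            communities = [c for c in communities if c]
            expected = nx.community.modularity(g, communities, weight=None)
            assert modularity(g, part) == pytest.approx(expected, abs=1e-12)

    def test_uncovered_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(DataError):
            modularity(g, {0: 0, 1: 0})

    def test_q_in_valid_range(self):
        g, truth, _ = make_planted_network(4, 8, 0.8, 0.02, seed=2)
        q = modularity(g, truth)
        assert -0.5 <= q <= 1.0


class TestGirvanNewman:
    def test_barbell_splits_at_bridge(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
        g.add_edges_from(itertools.combinations(["b1", "b2", "b3", "b4"], 2))
        g.add_edge("a1", "b1")
        part = girvan_newman_cluster(g)
        clusters = {frozenset(c) for c in part.clusters().values()}
        assert clusters == {frozenset({"a1", "a2", "a3", "a4"}),
                            frozenset({"b1", "b2", "b3", "b4"})}

    def test_complete_graph_stays_single_cluster(self):
        part = girvan_newman_cluster(nx.complete_graph(5))
        assert part.n_clusters == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-15)

    def test_deterministic(self):
        g, _, _ = make_planted_network(3, 8, 0.7, 0.05, seed=3)
        core = max(nx.connected_components(g), key=len)
        sub = g.subgraph(core).copy()
        p1 = girvan_newman_cluster(sub)
        p2 = girvan_newman_cluster(sub)
        assert p1.assignment == p2.assignment

    def test_disconnected_input_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(DataError):
            girvan_newman_cluster(g)

    def test_recovers_planted_modules(self):
        g, truth, _ = make_planted_network(4, 25, 0.3, 0.01, seed=17)
        core = max(nx.connected_components(g), key=len)
        sub = g.subgraph(core).copy()
        part = girvan_newman_cluster(sub)
        ari = _adjusted_rand(
            [truth[n] for n in sorted(sub.nodes)],
            [part.assignment[n] for n in sorted(sub.nodes)],
        )
        assert ari >= 0.9


def _adjusted_rand(labels_a, labels_b):
    """Adjusted Rand index from the pair-counting contingency table."""
    from scipy.special import comb

    a_ids, b_ids = sorted(set(labels_a)), sorted(set(labels_b))
    table = np.zeros((len(a_ids), len(b_ids)))
    for la, lb in zip(labels_a, labels_b):
        table[a_ids.index(la), b_ids.index(lb)] += 1
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(len(labels_a), 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestRewireNull:
    def test_star_graph_cannot_rewire(self):
        star = nx.star_graph(5)
        ens = rewire_null(star, n_iter=5, seed=1)
        for g in ens.graphs:
            assert set(g.edges()) == set(star.edges())

    def test_degree_sequence_preserved_in_all_permutations(self):
        g, _, _ = make_planted_network(3, 10, 0.4, 0.05, seed=8)
        ens = rewire_null(g, n_iter=100, seed=2)
        original = sorted(d for _, d in g.degree())
        assert len(ens.graphs) == 100
        for perm in ens.graphs:
            assert sorted(d for _, d in perm.degree()) == original
            assert not list(nx.selfloop_edges(perm))

    def test_cycle_rewires_to_different_edge_set(self):
        g = nx.cycle_graph(6)
        ens = rewire_null(g, n_iter=10, seed=3)
        assert any(set(p.edges()) != set(g.edges()) for p in ens.graphs)

    def test_too_few_edges_rejected(self):
        with pytest.raises(DataError):
            rewire_null(nx.Graph([(0, 1)]), n_iter=2, seed=0)


class TestCoannotation:
    def test_fully_annotated_term_has_fraction_one(self):
        g = nx.complete_graph(6)
        assert coannotation_fraction(g, set(g.nodes)) == 1.0

    def test_planted_terms_exceed_null_mean(self):
        g, _, annot = make_planted_network(4, 15, 0.5, 0.02, seed=12)
        null = rewire_null(g, n_iter=30, seed=5)
        result = coannotation_statistic(g, annot, null, min_proteins=0)
        for term, obs in result.per_term_observed.items():
            assert obs > result.per_term_null[term].mean()

    def test_random_annotations_are_calibrated(self):
        g, _, _ = make_planted_network(1, 60, 0.12, 0.01, seed=22)
        rng = np.random.default_rng(14)
        annot = AnnotationSet()
        nodes = sorted(g.nodes)
        for t in range(20):
            annot.add(f"t{t}", rng.choice(nodes, size=20, replace=False))
        null = rewire_null(g, n_iter=60, seed=6)
        result = coannotation_statistic(g, annot, null, min_proteins=0)
        inside = 0
        for term, obs in result.per_term_observed.items():
            lo, hi = np.percentile(result.per_term_null[term], [2.5, 97.5])
            inside += lo <= obs <= hi
        assert inside >= 0.9 * len(result.per_term_observed)

    def test_term_without_annotated_nodes_skipped(self):
        g = nx.path_graph(4)
        annot = AnnotationSet()
        annot.add("present", {0, 1})
        annot.add("absent", {"nowhere"})
        null = rewire_null(nx.cycle_graph(4), n_iter=3, seed=0)
        result = coannotation_statistic(g, annot, null, terms=["present", "absent"])
        assert result.skipped_terms == ["absent"]


class TestPathDistance:
    def test_clique_within_mean_one(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        annot = AnnotationSet()
        annot.add("t", {"a", "b", "c", "d"})
        res = path_distance_statistic(g, annot, "t")
        assert res["mean_within"] == 1.0

    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        annot = AnnotationSet()
        annot.add("t", {"A", "B"})
        res = path_distance_statistic(g, annot, "t")
        assert res["mean_within"] == 1.0
        # A-C=2, A-D=3, B-C=1, B-D=2 -> mean 2
        assert res["mean_between"] == 2.0

    def test_planted_terms_are_closer_within(self):
        g, _, annot = make_planted_network(3, 12, 0.6, 0.03, seed=19)
        core = max(nx.connected_components(g), key=len)
        sub = g.subgraph(core).copy()
        for term in annot:
            if len(annot[term] & core) >= 2:
                res = path_distance_statistic(sub, annot, term)
                assert res["mean_within"] < res["mean_between"]


class TestTermEnrichment:
    def test_cluster_equal_to_term_is_most_enriched(self):
        annot = AnnotationSet()
        annot.add("hit", {f"n{i}" for i in range(10)})
        annot.add("other", {f"m{i}" for i in range(10)})
        background = {f"n{i}" for i in range(10)} | {f"m{i}" for i in range(10)}
        df = term_enrichment({f"n{i}" for i in range(10)}, annot, background)
        assert df.iloc[0]["term"] == "hit"
        assert df.iloc[0]["pvalue"] < df[df.term == "other"]["pvalue"].iloc[0]

    def test_absent_term_not_enriched(self):
        annot = AnnotationSet()
        annot.add("t", {f"m{i}" for i in range(5)})
        cluster = {f"n{i}" for i in range(5)}
        background = cluster | {f"m{i}" for i in range(5)}
        df = term_enrichment(cluster, annot, background)
        row = df[df.term == "t"].iloc[0]
        assert row["fold"] <= 1.0
        assert row["pvalue"] >= 0.5

    def test_fisher_p_matches_hypergeometric_tail(self):
        # table (8,2,2,8): P = sum over k >= 8 of hypergeom pmf
        from scipy.stats import hypergeom

        annot = AnnotationSet()
        term_members = {f"a{i}" for i in range(8)} | {f"b{i}" for i in range(2)}
        annot.add("t", term_members)
        cluster = {f"a{i}" for i in range(8)} | {f"c{i}" for i in range(2)}
        background = {f"{x}{i}" for x in "abc" for i in range(10)}
        background |= cluster | term_members
        df = term_enrichment(cluster, annot, background)
        row = df[df.term == "t"].iloc[0]
        M, n, N = len(background), len(term_members & background), len(cluster)
        expected = sum(hypergeom.pmf(k, M, n, N) for k in range(8, min(n, N) + 1))
        assert row["pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_background_must_contain_cluster(self):
        annot = AnnotationSet()
        annot.add("t", {"a"})
        with pytest.raises(DataError):
            term_enrichment({"a", "b"}, annot, {"a"})
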