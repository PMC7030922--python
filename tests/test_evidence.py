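"""Confidence tiers, database overlap, replicate agreement, and network
reproducibility statistics."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlmap.errors import DataError, DegenerateInputError
from xlmap.evidence import (
    abundance_lysine_correlation,
    classify_tier,
    cluster_consistency,
    neighbor_agreement,
    pair_overlap,
    replicate_overlap,
)
from xlmap.io import CrossLink, CrossLinkDataset, EvidenceRecord, ProteinRecord
from xlmap.network import ClusterPartition, rewire_null
from xlmap.synthetic import make_evidence_db, make_planted_network


class TestClassifyTier:
    @pytest.mark.parametrize(
        "source,score,low_throughput,expected",
        [
            ("string", 399, False, "low"),
            ("string", 400, False, "medium"),
            ("string", 699.9, False, "medium"),
            ("string", 700, False, "high"),
            ("string", 1000, False, "high"),
            ("string", None, False, "low"),
            ("inweb", None, False, "low"),
            ("inweb", 0.19, False, "low"),
            ("inweb", 0.2, False, "medium"),
            ("inweb", 0.69, False, "medium"),
            ("inweb", 0.7, False, "high"),
            ("biogrid", None, True, "high"),
            ("biogrid", None, False, "low"),
        ],
    )
    def test_boundary_truth_table(self, source, score, low_throughput, expected):
        rec = EvidenceRecord("A", "B", source, score, low_throughput)
        assert classify_tier(rec) == expected

    @given(
        source=st.sampled_from(["string", "inweb", "biogrid"]),
        score=st.one_of(st.none(), st.floats(min_value=0, max_value=2000,
                                             allow_nan=False)),
        low_throughput=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_total_and_deterministic_over_score_domain(self, source, score, low_throughput):
        rec = EvidenceRecord("A", "B", source, score, low_throughput)
        tier = classify_tier(rec)
        assert tier in ("low", "medium", "high")
        assert classify_tier(rec) == tier


class TestPairOverlap:
    def test_no_evidence_all_fractions_zero(self):
        report = pair_overlap([("A", "B")], [])
        assert report.fraction_in_any_db == 0.0
        assert report.fraction_high_confidence == 0.0

    def test_uniform_high_scores_give_full_overlap(self):
        pairs = [("A", "B"), ("C", "D")]
        evidence = [EvidenceRecord(a, b, "string", 800) for a, b in pairs]
        report = pair_overlap(pairs, evidence)
        assert report.fraction_in_any_db == 1.0
        assert report.fraction_high_confidence == 1.0

    def test_best_tier_wins_across_sources(self):
        evidence = [
            EvidenceRecord("A", "B", "string", 100),
            EvidenceRecord("A", "B", "biogrid", None, low_throughput=True),
        ]
        report = pair_overlap([("A", "B")], evidence)
        assert report.per_pair_tier[("A", "B")] == "high"

    def test_counts_are_nested(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(50)]
        evidence, _ = make_evidence_db(pairs[:30], (0.4, 0.3, 0.3), seed=3)
        report = pair_overlap(pairs, evidence)
        assert report.n_high_confidence <= report.n_in_any_db <= report.n_pairs

    def test_fractions_match_generator_truth(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(400)]
        evidence, truth = make_evidence_db(pairs, (0.5, 0.3, 0.2), seed=9)
        report = pair_overlap(pairs, evidence)
        assert report.fraction_in_any_db == 1.0
        expected_high = sum(t == "high" for t in truth.values()) / len(pairs)
        assert report.fraction_high_confidence == pytest.approx(expected_high)

    def test_xl_count_distributions_split_by_membership(self):
        pairs = [("A", "B"), ("C", "D")]
        evidence = [EvidenceRecord("A", "B", "string", 800)]
        counts = {("A", "B"): 5, ("C", "D"): 1}
        report = pair_overlap(pairs, evidence, xl_counts=counts)
        assert report.xl_counts_in_db == [5]
        assert report.xl_counts_not_in_db == [1]


def _dataset_from_pairs(pairs, name):
    return CrossLinkDataset(
        [CrossLink(a, 10, b, 10, samples=frozenset({name})) for a, b in pairs],
        name=name,
    )


class TestReplicateOverlap:
    def test_identical_datasets_all_maximal(self):
        ds = _dataset_from_pairs([("A", "B"), ("C", "D")], "r")
        summary = replicate_overlap([ds, ds, ds])
        assert all(m == 3 for m in summary.multiplicity.values())

    def test_disjoint_datasets_all_singletons(self):
        d1 = _dataset_from_pairs([("A", "B")], "r1")
        d2 = _dataset_from_pairs([("C", "D")], "r2")
        summary = replicate_overlap([d1, d2])
        assert all(m == 1 for m in summary.multiplicity.values())

    def test_designed_overlap_histogram(self):
        # 5 pairs in all three, 3 pairs in two, 7 pairs in one
        all3 = [(f"X{i}", f"Y{i}") for i in range(5)]
        two = [(f"T{i}", f"U{i}") for i in range(3)]
        one = [(f"O{i}", f"P{i}") for i in range(7)]
        d1 = _dataset_from_pairs(all3 + two + one[:3], "r1")
        d2 = _dataset_from_pairs(all3 + two + one[3:5], "r2")
        d3 = _dataset_from_pairs(all3 + one[5:], "r3")
        summary = replicate_overlap([d1, d2, d3])
        assert summary.histogram == {1: 7, 2: 3, 3: 5}

    def test_order_invariant(self):
        d1 = _dataset_from_pairs([("A", "B"), ("C", "D")], "r1")
        d2 = _dataset_from_pairs([("A", "B")], "r2")
        d3 = _dataset_from_pairs([("E", "F")], "r3")
        s1 = replicate_overlap([d1, d2, d3])
        s2 = replicate_overlap([d3, d1, d2])
        assert s1.multiplicity == s2.multiplicity

    def test_histogram_counts_sum_to_pairs(self):
        d1 = _dataset_from_pairs([("A", "B"), ("C", "D")], "r1")
        d2 = _dataset_from_pairs([("A", "B"), ("E", "F")], "r2")
        summary = replicate_overlap([d1, d2])
        assert sum(summary.histogram.values()) == summary.n_pairs

    def test_needs_two_datasets(self):
        with pytest.raises(DataError):
            replicate_overlap([_dataset_from_pairs([("A", "B")], "r")])


class TestNeighborAgreement:
    def test_identical_networks_fully_direct(self):
        g = nx.karate_club_graph()
        assert neighbor_agreement(g, g) == (1.0, 0.0, 0.0)

    def test_common_neighbor_is_indirect(self):
        net_a = nx.Graph([("A", "C")])
        net_b = nx.Graph([("A", "B"), ("B", "C")])
        direct, indirect, unconnected = neighbor_agreement(net_a, net_b)
        assert (direct, indirect, unconnected) == (0.0, 1.0, 0.0)

    def test_fractions_sum_to_one(self):
        g1, _, _ = make_planted_network(3, 10, 0.4, 0.05, seed=31)
        g2, _, _ = make_planted_network(3, 10, 0.4, 0.05, seed=32)
        fracs = neighbor_agreement(g1, g2)
        assert sum(fracs) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_per_edge_check(self):
        g1, _, _ = make_planted_network(2, 12, 0.35, 0.08, seed=41)
        g2, _, _ = make_planted_network(2, 12, 0.35, 0.08, seed=42)
        shared = set(g1.nodes) & set(g2.nodes)
        n_d = n_i = n_u = 0
        for u, v in g1.edges():
            if u not in shared or v not in shared:
                continue
            if g2.has_edge(u, v):
                n_d += 1
            elif any(g2.has_edge(u, w) and g2.has_edge(w, v) for w in g2.nodes):
                n_i += 1
            else:
                n_u += 1
        total = n_d + n_i + n_u
        assert neighbor_agreement(g1, g2) == (n_d / total, n_i / total, n_u / total)

    def test_disjoint_node_sets_rejected(self):
        with pytest.raises(DataError):
            neighbor_agreement(nx.Graph([("A", "B")]), nx.Graph([("X", "Y")]))


class TestClusterConsistency:
    def test_self_consistency_beats_null(self):
        g, truth, _ = make_planted_network(4, 12, 0.6, 0.02, seed=27)
        null = rewire_null(g, n_iter=30, seed=1)
        result = cluster_consistency(g, truth, null)
        obs_mean = np.mean(list(result.per_node_fraction.values()))
        assert obs_mean > result.null_fractions.mean()
        assert result.ks_pvalue < 0.01

    def test_shuffled_labels_match_null(self):
        g, truth, _ = make_planted_network(4, 12, 0.6, 0.02, seed=27)
        rng = np.random.default_rng(2)
        labels = list(truth.values())
        rng.shuffle(labels)
        shuffled = dict(zip(truth.keys(), labels))
        null = rewire_null(g, n_iter=30, seed=3)
        result = cluster_consistency(g, shuffled, null)
        assert result.ks_pvalue > 0.01

    def test_unlabelled_network_rejected(self):
        g = nx.path_graph(["x", "y"])
        null = rewire_null(nx.cycle_graph(4), n_iter=2, seed=0)
        with pytest.raises(DataError):
            cluster_consistency(g, {"a": 0}, null)


class TestAbundanceLysineCorrelation:
    def _world(self, n, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        sequences, abundances, links = {}, {}, []
        for i in range(n):
            acc = f"P{i:03d}"
            sequences[acc] = ProteinRecord(acc, "K" * 20 + "A" * 30)
            abund = float(10 ** rng.uniform(1, 4))
            abundances[acc] = abund
            # cross-linked lysine count follows a power of corrected abundance
            n_linked = int(np.clip(round((abund / 20) ** 0.3 * 10 ** rng.normal(0, noise_sd)), 1, 20))
            partner = f"Q{i:03d}"
            sequences[partner] = ProteinRecord(partner, "A" * 50)
            for k in range(n_linked):
                links.append(CrossLink(acc, k + 1, partner, 30))
        return CrossLinkDataset(links), abundances, sequences

    def test_noise_free_relation_gives_r2_one(self):
        # counts chosen so log10(count) is exactly linear in the corrected abundance
        sequences, abundances, links = {}, {}, []
        for i, count in enumerate([1, 2, 4, 8, 16]):
            acc, partner = f"P{i}", f"Q{i}"
            sequences[acc] = ProteinRecord(acc, "K" * 20 + "A" * 30)
            sequences[partner] = ProteinRecord(partner, "A" * 50)
            abundances[acc] = 20.0 * count ** (1 / 0.3)
            for k in range(count):
                links.append(CrossLink(acc, k + 1, partner, 30))
        r2, r, n = abundance_lysine_correlation(CrossLinkDataset(links), abundances, sequences)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert n == 5

    def test_constant_abundance_undefined(self):
        ds, abundances, sequences = self._world(10, noise_sd=0.1)
        flat = {a: 100.0 for a in abundances}
        with pytest.raises(DegenerateInputError):
            abundance_lysine_correlation(ds, flat, sequences)

    def test_matches_closed_form_pearson(self):
        ds, abundances, sequences = self._world(50, noise_sd=0.4, seed=5)
        r2, r, n = abundance_lysine_correlation(ds, abundances, sequences)
        linked = {}
        for link in ds:
            linked.setdefault(link.protein_a, set()).add(link.pos_a)
            linked.setdefault(link.protein_b, set()).add(link.pos_b)
        xs, ys = [], []
        for acc in sorted(linked):
            if acc not in abundances or acc not in sequences:
                continue
            n_lys = sequences[acc].sequence.count("K")
            if n_lys == 0:
                continue
            xs.append(np.log10(abundances[acc] / n_lys))
            ys.append(np.log10(len(linked[acc])))
        xs, ys = np.array(xs), np.array(ys)
        cov = ((xs - xs.mean()) * (ys - ys.mean())).sum()
        expected_r = cov / np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        assert r == pytest.approx(expected_r, abs=1e-9)
        assert r2 == pytest.approx(expected_r**2, abs=1e-9)

    def test_too_few_proteins_rejected(self):
        ds, abundances, sequences = self._world(2, noise_sd=0.1)
        with pytest.raises(DegenerateInputError):
            abundance_lysine_correlation(ds, abundances, sequences)
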