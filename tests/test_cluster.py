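import itertools

import networkx as nx
import numpy as np
import pytest

from divscan.cluster import (
    all_pairs_scores,
    build_graph,
    filter_divlike_clusters,
    girvan_newman,
    karlin_altschul_pvalue,
    pairwise_score,
    recover_planted_clusters,
    smith_waterman_score,
)
from divscan.errors import ContractError, ParameterError
from divscan.seqio import SequenceRecord
from divscan.synth import generate_sequence_families
from oracle_helpers import exhaustive_max_modularity, sw_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, lo=8, hi=20):
    return "".join(AA[i] for i in rng.integers(0, 20, size=rng.integers(lo, hi)))


class TestSmithWaterman:
    def test_textbook_pair_matches_independent_dp_oracle(self):
        # frozen from the DP oracle: BLOSUM62, gap open 11 / extend 1
        assert sw_oracle("HEAGAWGHEE", "PAWHEAE") == 17.0
        assert smith_waterman_score("HEAGAWGHEE", "PAWHEAE") == 17.0

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = _random_seq(rng), _random_seq(rng)
            assert smith_waterman_score(a, b) == sw_oracle(a, b)

    def test_self_alignment_of_repeat_free_sequence_is_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        seq = "MKLVINDEQRSTGHWYFACP"  # all 20 letters once: repeat-free
        assert smith_waterman_score(seq, seq) == sum(mat[c, c] for c in seq)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = _random_seq(rng), _random_seq(rng)
            assert smith_waterman_score(a, b) == smith_waterman_score(b, a)

    def test_unknown_matrix_rejected(self):
        a = SequenceRecord("a", "MKLV")
        b = SequenceRecord("b", "MKLV")
        with pytest.raises(ParameterError):
            pairwise_score(a, b, matrix="NOSUCH62")


class TestPValues:
    def test_p_value_decreases_with_score(self):
        ps = [karlin_altschul_pvalue(s, 300, 300)[1] for s in range(20, 200, 10)]
        assert ps == sorted(ps, reverse=True)
        assert all(0 < p <= 1 for p in ps)

    def test_edge_symmetric_in_arguments(self, random_records):
        a, b = random_records(2, length=80, seed=9)
        assert pairwise_score(a, b).p_value == pairwise_score(b, a).p_value

    def test_no_self_edges(self):
        a = SequenceRecord("a", "MKLV")
        with pytest.raises(ContractError):
            pairwise_score(a, a)


class TestGraph:
    def test_identical_long_sequences_pass_the_threshold(self, random_records):
        (a,) = random_records(1, length=300, seed=4)
        b = SequenceRecord("b", a.sequence)
        edge = pairwise_score(a, b)
        assert edge.p_value <= 1e-15
        graph = build_graph([a, b], [edge])
        assert graph.has_edge("r0", "b")

    def test_unrelated_sequences_make_no_edge(self, random_records):
        a, b = random_records(2, length=100, seed=8)
        edge = pairwise_score(a, b)
        assert edge.p_value > 1e-15
        graph = build_graph([a, b], [edge])
        assert graph.number_of_edges() == 0
        assert set(graph.nodes()) == {"r0", "r1"}  # isolated nodes kept

    def test_permissive_threshold_keeps_every_edge(self, random_records):
        records = random_records(5, length=60, seed=3)
        edges = all_pairs_scores(records)
        graph = build_graph(records, edges, threshold=1.0)
        assert graph.number_of_edges() == len(edges)

    def test_edge_set_monotone_in_threshold(self, random_records):
        records = random_records(6, length=80, seed=12)
        edges = all_pairs_scores(records)
        previous = None
        for threshold in (1e-15, 1e-5, 1e-2, 1.0):
            current = set(build_graph(records, edges, threshold).edges())
            if previous is not None:
                assert previous <= current
            previous = current


def _battery():
    """Community-structured graphs with <= 8 nodes."""
    graphs = {}
    g = nx.Graph()
    g.add_edges_from(
        [(i, j) for i in range(4) for j in range(i + 1, 4)]
        + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        + [(3, 4)]
    )
    graphs["two_4cliques_bridge"] = g
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    graphs["two_triangles_bridge"] = g
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2)])
    graphs["triangle"] = g
    g = nx.Graph()
    g.add_nodes_from(range(5))
    graphs["edgeless"] = g
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
    graphs["path6"] = g
    g = nx.Graph()
    g.add_edges_from([(0, i) for i in range(1, 6)])
    graphs["star6"] = g
    g = nx.Graph()
    g.add_edges_from(
        [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6), (5, 7),
         (6, 7), (3, 4)]
    )
    graphs["two_diamonds_bridge"] = g
    return graphs


class TestGirvanNewman:
    @pytest.mark.parametrize("name", sorted(_battery()))
    def test_equals_exhaustive_max_modularity(self, name):
        graph = _battery()[name]
        partition = girvan_newman(graph)
        assert partition.modularity == pytest.approx(
            exhaustive_max_modularity(graph), abs=1e-9
        )
        assert -0.5 <= partition.modularity <= 1

    def test_two_cliques_split_at_the_bridge(self):
        partition = girvan_newman(_battery()["two_4cliques_bridge"])
        clusters = partition.clusters()
        assert sorted(sorted(c) for c in clusters) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_triangle_stays_whole(self):
        partition = girvan_newman(_battery()["triangle"])
        assert partition.n_clusters == 1
        assert partition.modularity == 0.0

    def test_edgeless_graph_gives_singletons(self):
        partition = girvan_newman(_battery()["edgeless"])
        assert partition.n_clusters == 5
        assert partition.modularity == 0.0

    def test_deterministic(self):
        graph = _battery()["two_diamonds_bridge"]
        assert girvan_newman(graph).assignment == girvan_newman(graph).assignment


class TestClusterFilter:
    def _partition(self, sizes):
        assignment = {}
        node = 0
        for idx, size in enumerate(sizes):
            for _ in range(size):
                assignment[f"n{node}"] = idx
                node += 1
        from divscan.cluster import ClusterPartition

        return ClusterPartition(assignment, 0.5)

    def test_exact_half_is_selected(self):
        partition = self._partition([4])
        hits = {"n0": True, "n1": True, "n2": False, "n3": False}
        selected, fractions = filter_divlike_clusters(partition, hits)
        assert selected == [0] and fractions[0] == 0.5

    def test_below_half_not_selected(self):
        partition = self._partition([3])
        hits = {"n0": True, "n1": False, "n2": False}
        selected, fractions = filter_divlike_clusters(partition, hits)
        assert selected == [] and fractions[0] == pytest.approx(1 / 3)

    def test_background_cluster_scores_zero(self):
        partition = self._partition([2, 3])
        hits = {f"n{i}": i < 2 for i in range(5)}
        selected, fractions = filter_divlike_clusters(partition, hits)
        assert selected == [0] and fractions[1] == 0.0

    def test_missing_record_rejected(self):
        partition = self._partition([2])
        with pytest.raises(ContractError):
            filter_divlike_clusters(partition, {"n0": True})


class TestPlantedRecovery:
    def test_three_families_recovered_exactly(self):
        records, labels = generate_sequence_families(3, 6, length=250, seed=42)
        ari, partition = recover_planted_clusters(records, labels)
        assert ari == 1.0
        assert partition.n_clusters == 3

    def test_single_family_is_one_cluster(self):
        records, labels = generate_sequence_families(1, 5, length=250, seed=7)
        ari, partition = recover_planted_clusters(records, labels)
        assert ari == 1.0
        assert partition.n_clusters == 1

    def test_shuffled_labels_score_near_zero(self):
        from sklearn.metrics import adjusted_rand_score

        records, labels = generate_sequence_families(3, 6, length=250, seed=42)
        ari, partition = recover_planted_clusters(records, labels)
        rng = np.random.default_rng(0)
        values = list(labels.values())
        rng.shuffle(values)
        shuffled = dict(zip(labels.keys(), values))
        predicted = [partition.assignment[r.id] for r in records]
        truth = [shuffled[r.id] for r in records]
        assert abs(adjusted_rand_score(truth, predicted)) < 0.3
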