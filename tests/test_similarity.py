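import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner
from hypothesis import given, settings
from hypothesis import strategies as st

from rwrhe.containers import (
    AssociationMatrix,
    EdgeScoreTable,
    FingerprintSet,
    SimilarityMatrix,
    TargetRecord,
)
from rwrhe.similarity import (
    common_neighbor_similarity,
    edge_score_similarity,
    gip_kernel,
    logistic_transform,
    sequence_similarity,
    tanimoto_similarity,
)

C, D = -15.0, math.log(9999.0)


def fps(*vectors):
    return FingerprintSet(
        ids=[f"r{i}" for i in range(len(vectors))], bits=np.array(vectors)
    )


class TestTanimoto:
    def test_identical_nonzero_vectors_have_similarity_one(self):
        s = tanimoto_similarity(fps([1, 0, 1], [1, 0, 1]))
        assert s.values[0, 1] == 1.0

    def test_disjoint_bit_sets_have_similarity_zero(self):
        s = tanimoto_similarity(fps([1, 1, 0, 0], [0, 0, 1, 1]))
        assert s.values[0, 1] == 0.0

    def test_partial_overlap_hand_value(self):
        # overlap 1, sizes 2 and 2: 1 / (2 + 2 - 1) = 1/3
        s = tanimoto_similarity(fps([1, 1, 0], [1, 0, 1]))
        assert s.values[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_all_zero_fingerprint_gets_zero_row_and_unit_diagonal(self):
        s = tanimoto_similarity(fps([0, 0, 0], [1, 0, 1]))
        assert s.values[0, 1] == 0.0
        assert s.values[0, 0] == 1.0


class TestLogisticTransform:
    def test_reference_anchor_values(self):
        """L(0) = 1e-4 exactly and L(0.3) < 0.01 define the c, d choice."""
        s = SimilarityMatrix(
            ids=["a", "b", "c"],
            values=np.array([[1.0, 0.0, 0.3], [0.0, 1.0, 1.0], [0.3, 1.0, 1.0]]),
            tag="Sr1",
        )
        out = logistic_transform(s, C, D)
        assert out.values[0, 1] == pytest.approx(1e-4, rel=1e-12)
        assert out.values[0, 2] < 0.01
        # L(1) evaluated independently from the closed form
        assert out.values[1, 2] == pytest.approx(1.0 / (1.0 + 9999.0 * math.exp(-15.0)), rel=1e-12)

    def test_diagonal_forced_to_one(self):
        s = SimilarityMatrix(ids=["a", "b"], values=np.eye(2), tag="Sr1")
        out = logistic_transform(s, C, D)
        assert np.array_equal(np.diag(out.values), [1.0, 1.0])

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_monotone_for_negative_c(self, s1, s2):
        lo, hi = sorted((s1, s2))
        if hi - lo < 1e-9:  # below float resolution of the transform
            return
        m = SimilarityMatrix(
            ids=["a", "b", "c"],
            values=np.array([[1.0, lo, hi], [lo, 1.0, 0.0], [hi, 0.0, 1.0]]),
            tag="Sr1",
        )
        out = logistic_transform(m, C, D)
        assert out.values[0, 1] < out.values[0, 2]


class TestGipKernel:
    def test_identical_profiles_have_similarity_one(self):
        A = AssociationMatrix(["r1", "r2"], ["t1", "t2"], np.array([[1, 0], [1, 0]]))
        s = gip_kernel(A, "rows")
        assert s.values[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_orthogonal_profiles_hand_value(self):
        # mean squared profile norm 1 so gamma = 1; distance^2 = 2 -> e^-2
        A = AssociationMatrix(["r1", "r2"], ["t1", "t2"], np.array([[1, 0], [0, 1]]))
        s = gip_kernel(A, "rows", gamma_prime=1.0)
        assert s.values[0, 1] == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_doubling_bandwidth_squares_off_diagonal_similarity(self):
        rng = np.random.default_rng(3)
        A = AssociationMatrix(
            [f"r{i}" for i in range(6)],
            [f"t{j}" for j in range(9)],
            (rng.random((6, 9)) < 0.4).astype(np.uint8),
        )
        s1 = gip_kernel(A, "rows", gamma_prime=1.0).values
        s2 = gip_kernel(A, "rows", gamma_prime=2.0).values
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(s2[off], s1[off] ** 2, atol=1e-12)

    @pytest.mark.parametrize("axis", ["rows", "cols"])
    def test_matches_brute_force_elementwise_oracle(self, axis):
        rng = np.random.default_rng(11)
        for _ in range(10):
            nr, nt = rng.integers(2, 21, size=2)
            values = (rng.random((nr, nt)) < 0.35).astype(np.uint8)
            if values.sum() == 0:
                values[0, 0] = 1
            A = AssociationMatrix(
                [f"r{i}" for i in range(nr)], [f"t{j}" for j in range(nt)], values
            )
            profiles = values if axis == "rows" else values.T
            n = profiles.shape[0]
            gamma = 1.0 / np.mean([(p.astype(float) ** 2).sum() for p in profiles])
            expected = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    d2 = float(((profiles[i].astype(float) - profiles[j]) ** 2).sum())
                    expected[i, j] = math.exp(-gamma * d2)
            got = gip_kernel(A, axis).values
            assert np.allclose(got, expected, atol=1e-12)


class TestSequenceSimilarity:
    def test_identical_sequences_have_similarity_one(self):
        targets = [TargetRecord("T1", "MKVLYT"), TargetRecord("T2", "MKVLYT")]
        s = sequence_similarity(targets)
        assert s.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_unalignable_sequences_have_similarity_zero(self):
        # match +2, mismatch -1, gap -1: no positive-scoring local alignment
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        targets = [TargetRecord("T1", "AAAA"), TargetRecord("T2", "CCCC")]
        s = sequence_similarity(targets, aligner=aligner)
        assert s.values[0, 1] == 0.0

    def test_normalized_scores_are_bounded_by_one(self):
        rng = np.random.default_rng(5)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        targets = [
            TargetRecord(f"T{i}", "".join(rng.choice(aa, size=rng.integers(10, 31))))
            for i in range(8)
        ]
        s = sequence_similarity(targets)
        assert np.all(s.values <= 1.0 + 1e-12)
        assert np.all(s.values >= 0.0)

    def test_missing_sequence_contributes_zero_off_diagonal(self):
        targets = [TargetRecord("T1", "MKVLYT"), TargetRecord("T2", None)]
        s = sequence_similarity(targets)
        assert s.values[0, 1] == 0.0
        assert s.values[1, 1] == 1.0


class TestEdgeScoreSimilarity:
    def test_listed_pair_and_symmetry(self):
        s = edge_score_similarity(
            EdgeScoreTable(edges=[("t1", "t2", 0.8)]), ["t1", "t2", "t3"]
        )
        assert s.values[0, 1] == 0.8 == s.values[1, 0]
        assert s.values[0, 2] == 0.0  # unlisted pair

    def test_empty_edge_table_gives_identity(self):
        s = edge_score_similarity(EdgeScoreTable(edges=[]), ["t1", "t2"])
        assert np.array_equal(s.values, np.eye(2))

    def test_unknown_target_edge_is_dropped(self):
        s = edge_score_similarity(
            EdgeScoreTable(edges=[("t1", "zz", 0.8)]), ["t1", "t2"]
        )
        assert np.array_equal(s.values, np.eye(2))


def _brute_force_common_neighbor(edges, ids, threshold):
    neighbors = {t: set() for t in ids}
    for a, b, score in edges:
        if score > threshold and a in neighbors and b in neighbors and a != b:
            neighbors[a].add(b)
            neighbors[b].add(a)
    n = len(ids)
    out = np.zeros((n, n))
    for i, ti in enumerate(ids):
        for j, tj in enumerate(ids):
            if i == j:
                continue
            for z in neighbors[ti] & neighbors[tj]:
                out[i, j] += 1.0 / len(neighbors[z])
    out[out > 1.0] = 0.99
    np.fill_diagonal(out, 1.0)
    return out


class TestCommonNeighborSimilarity:
    def test_single_shared_neighbor_of_degree_two(self):
        edges = EdgeScoreTable(edges=[("i", "z", 0.9), ("j", "z", 0.9)])
        s = common_neighbor_similarity(edges, ["i", "j", "z"], threshold=0.4)
        assert s.values[0, 1] == pytest.approx(0.5)

    def test_sum_above_one_is_capped(self):
        # three shared neighbors, each of degree 2: 3 * 1/2 = 1.5 -> 0.99
        edges = EdgeScoreTable(
            edges=[(a, z, 0.9) for a in ("i", "j") for z in ("z1", "z2", "z3")]
        )
        s = common_neighbor_similarity(
            edges, ["i", "j", "z1", "z2", "z3"], threshold=0.4
        )
        assert s.values[0, 1] == 0.99

    def test_exact_sum_of_one_is_not_capped(self):
        # two shared neighbors of degree 2: 1/2 + 1/2 = 1, cap is strict
        edges = EdgeScoreTable(
            edges=[(a, z, 0.9) for a in ("i", "j") for z in ("z1", "z2")]
        )
        s = common_neighbor_similarity(edges, ["i", "j", "z1", "z2"], threshold=0.4)
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_no_common_neighbors_is_zero(self):
        edges = EdgeScoreTable(edges=[("i", "z1", 0.9), ("j", "z2", 0.9)])
        s = common_neighbor_similarity(edges, ["i", "j", "z1", "z2"], threshold=0.4)
        assert s.values[0, 1] == 0.0

    def test_threshold_is_strict(self):
        edges = EdgeScoreTable(edges=[("i", "z", 0.4), ("j", "z", 0.9)])
        s = common_neighbor_similarity(edges, ["i", "j", "z"], threshold=0.4)
        assert s.values[0, 1] == 0.0  # the 0.4-score edge is not a neighbor

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 31))
            ids = [f"t{i}" for i in range(n)]
            edges = [
                (ids[i], ids[j], float(rng.random()))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            got = common_neighbor_similarity(
                EdgeScoreTable(edges=edges), ids, threshold=0.4
            ).values
            expected = _brute_force_common_neighbor(edges, ids, 0.4)
            assert np.allclose(got, expected, atol=1e-12)


class TestMeasureInvariants:
    def test_all_measures_symmetric_with_unit_diagonal(self, default_measures):
        r_measures, t_measures = default_measures
        for tag, m in {**r_measures, **t_measures}.items():
            assert m.max_asymmetry() < 1e-12, tag
            assert np.allclose(np.diag(m.values), 1.0, atol=1e-12), tag

    def test_measure_values_lie_in_unit_interval(self, default_measures):
        r_measures, t_measures = default_measures
        for tag, m in {**r_measures, **t_measures}.items():
            assert m.values.min() >= 0.0, tag
            assert m.values.max() <= 1.0 + 1e-12, tag
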