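import itertools
import math

import numpy as np
import pytest

from hypermhc.errors import AsymmetricMap, RecordRejected, TooShort
from hypermhc.hypergraph import (
    BinaryContacts,
    binarize_contacts,
    build_hyperedges,
    hyperconv_forward,
    hyperconv_twostep,
    hypergraph_from_contacts,
    propagation_matrix,
)


def worked_example_map():
    """4-residue map with off-diagonal pair scores
    01:0.9 02:0.1 03:0.8 12:0.7 13:0.2 23:0.6."""
    A = np.eye(4)
    vals = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.8, (1, 2): 0.7, (1, 3): 0.2, (2, 3): 0.6}
    for (i, j), v in vals.items():
        A[i, j] = A[j, i] = v
    return A


def random_incidence(rng, n_max=8):
    """Random valid incidence structure built through the pipeline."""
    n = rng.integers(3, n_max + 1)
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return hypergraph_from_contacts(A, ratio=0.5)


class TestBinarize:
    def test_worked_example_top_half(self):
        C = binarize_contacts(worked_example_map(), ratio=0.5).C
        retained = {(i, j) for i in range(4) for j in range(i + 1, 4) if C[i, j]}
        assert retained == {(0, 1), (0, 3), (1, 2)}

    def test_ratio_one_is_all_ones(self):
        C = binarize_contacts(worked_example_map(), ratio=1.0).C
        assert np.array_equal(C, np.ones((4, 4), dtype=np.int8))

    def test_tie_break_is_lexicographic(self):
        A = np.ones((4, 4)) * 0.5
        np.fill_diagonal(A, 1.0)
        C = binarize_contacts(A, ratio=0.5).C
        retained = {(i, j) for i in range(4) for j in range(i + 1, 4) if C[i, j]}
        assert retained == {(0, 1), (0, 2), (0, 3)}  # smallest (i, j) first

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    @pytest.mark.parametrize("ratio", [0.1, 0.5, 0.9, 1.0])
    def test_exact_retention_count(self, n, ratio):
        rng = np.random.default_rng(n * 100 + int(ratio * 10))
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        C = binarize_contacts(A, ratio=ratio).C
        pairs = n * (n - 1) // 2
        assert np.triu(C, 1).sum() == math.ceil(ratio * pairs)

    def test_input_validation(self):
        with pytest.raises(AsymmetricMap):
            binarize_contacts(np.array([[1.0, 0.2], [0.9, 1.0]]))
        with pytest.raises(TooShort):
            binarize_contacts(np.array([[1.0]]))


class TestBuildHyperedges:
    def test_worked_example_enumeration(self):
        inc = build_hyperedges(binarize_contacts(worked_example_map(), 0.5))
        assert inc.edges == [
            frozenset({0, 1, 3}),
            frozenset({0, 1, 2}),
            frozenset({1, 2}),
            frozenset({0, 3}),
        ]
        assert inc.n_edges == 4
        assert inc.node_degrees.tolist() == [3, 3, 2, 2]
        assert inc.edge_degrees.tolist() == [3, 3, 2, 2]

    def test_identity_contacts_rejected(self):
        with pytest.raises(RecordRejected):
            build_hyperedges(BinaryContacts(np.eye(5, dtype=int)))

    def test_all_ones_collapses_to_single_edge(self):
        inc = build_hyperedges(BinaryContacts(np.ones((5, 5), dtype=int)))
        assert inc.n_edges == 1
        assert inc.edges[0] == frozenset(range(5))
        assert inc.node_degrees.tolist() == [1] * 5
        assert inc.edge_degrees.tolist() == [5]

    def test_exhaustive_small_matrices(self):
        """All symmetric binary C (unit diagonal) with N <= 4: dedup,
        rejection rule and degree reconciliation match set logic."""
        for n in (2, 3, 4):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in itertools.product((0, 1), repeat=len(pairs)):
                C = np.eye(n, dtype=int)
                for (i, j), b in zip(pairs, bits):
                    C[i, j] = C[j, i] = b
                expected_edges = []
                for i in range(n):
                    e = frozenset(np.flatnonzero(C[i]).tolist())
                    if e not in expected_edges:
                        expected_edges.append(e)
                if max(len(e) for e in expected_edges) < 2:
                    with pytest.raises(RecordRejected):
                        build_hyperedges(BinaryContacts(C))
                    continue
                inc = build_hyperedges(BinaryContacts(C))
                assert inc.edges == expected_edges
                # reconstructing edges from I reproduces the edge list
                rebuilt = [
                    frozenset(np.flatnonzero(inc.incidence[:, k]).tolist())
                    for k in range(inc.n_edges)
                ]
                assert rebuilt == expected_edges
                assert inc.node_degrees.tolist() == [
                    sum(i in e for e in expected_edges) for i in range(n)
                ]
                assert inc.edge_degrees.tolist() == [len(e) for e in expected_edges]


class TestHyperConv:
    def test_twostep_identity_incidence(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        I = np.eye(4)
        assert np.allclose(hyperconv_twostep(X, I, np.eye(3)), X)

    def test_twostep_single_all_node_edge(self):
        n, c = 5, np.array([2.0, -1.0, 0.5])
        X = np.tile(c, (n, 1))
        I = np.ones((n, 1))
        out = hyperconv_twostep(X, I, np.eye(3))
        assert np.allclose(out, n * X)

    def test_twostep_linearity_in_zero(self):
        rng = np.random.default_rng(0)
        inc = random_incidence(rng)
        out = hyperconv_twostep(
            np.zeros((inc.n_nodes, 3)), inc.incidence, rng.random((3, 3))
        )
        assert np.allclose(out, 0.0)

    def test_forward_two_node_worked_example(self):
        inc = build_hyperedges(BinaryContacts(np.ones((2, 2), dtype=int)))
        X = np.array([[2.0], [0.0]])
        out = hyperconv_forward(X, inc, np.eye(1), activation="identity")
        assert np.allclose(out, [[1.0], [1.0]])

    def test_fixed_point_and_operator_properties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            inc = random_incidence(rng)
            theta = propagation_matrix(inc)
            assert np.allclose(theta, theta.T, atol=1e-12)
            assert theta.min() >= 0
            v = np.sqrt(inc.node_degrees.astype(float))
            assert np.allclose(theta @ v, v, atol=1e-8)

    def test_forward_matches_normalized_twostep(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            inc = random_incidence(rng)
            X = rng.standard_normal((inc.n_nodes, 4))
            Phi = rng.standard_normal((4, 4))
            dv = inc.node_degrees.astype(float)
            de = inc.edge_degrees.astype(float)
            I = inc.incidence.astype(float)
            # edge aggregation on degree-scaled features, then node
            # aggregation with the inverse scalings
            M_E = (I * (1 / de)).T @ (X / np.sqrt(dv)[:, None]) @ Phi
            oracle = (I @ M_E) / np.sqrt(dv)[:, None]
            fused = hyperconv_forward(X, inc, Phi, activation="identity")
            assert np.max(np.abs(fused - oracle)) < 1e-8

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        inc = random_incidence(rng)
        n = inc.n_nodes
        X = rng.standard_normal((n, 3))
        Phi = rng.standard_normal((3, 3))
        out = hyperconv_forward(X, inc, Phi, activation="relu")
        perm = rng.permutation(n)
        from hypermhc.hypergraph import IncidenceStructure

        I_p = inc.incidence[perm]
        inc_p = IncidenceStructure(
            incidence=I_p,
            node_degrees=I_p.sum(axis=1),
            edge_degrees=I_p.sum(axis=0),
            edges=[frozenset(np.flatnonzero(I_p[:, k]).tolist()) for k in range(inc.n_edges)],
        )
        out_p = hyperconv_forward(X[perm], inc_p, Phi, activation="relu")
        assert np.allclose(out_p, out[perm])

    def test_triplet_serialization(self, tmp_path):
        inc = build_hyperedges(binarize_contacts(worked_example_map(), 0.5))
        path = tmp_path / "inc.tsv"
        inc.to_triplets(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == int(inc.edge_degrees.sum())
        assert lines[0] == "0\t0\t1"
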