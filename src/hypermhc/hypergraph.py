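"""Hypergraph construction from contact maps and hypergraph convolution.

A peptide's predicted contact map is binarized by keeping the top
fraction of off-diagonal pair scores (default 50%).  Each row ``i`` of
the binary map then defines a candidate hyperedge ``R_i = {n : C[i, n]
= 1}`` — residue ``i`` together with its spatial neighbourhood (the
diagonal is forced to 1, so every residue belongs at least to its own
edge).  Duplicate edges are removed (first occurrence kept); if no
surviving edge has two or more members, the pair carries no usable
structure and the record is rejected.

Message passing follows the standard node-edge-node hypergraph
convolution: unnormalized it is ``I (I^T X Phi)`` (edge aggregation
then node aggregation), and the production operator applies symmetric
degree normalization::

    X' = sigma( D_v^{-1/2} I D_e^{-1} I^T D_v^{-1/2} X Phi )

where ``D_v``/``D_e`` are node/edge degrees.  With sigma = identity
this operator has ``D_v^{1/2} 1`` as a fixed point, which the tests
exploit as an analytic invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AsymmetricMap, RecordRejected, ShapeError, TooShort

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "elu": lambda x: np.where(x > 0, x, np.expm1(x)),
}


@dataclass
class BinaryContacts:
    """Symmetric binary contact matrix with unit diagonal."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ShapeError(f"C must be square, got {C.shape}")
        if not np.array_equal(C, C.T):
            raise AsymmetricMap("binary contact matrix must be symmetric")
        if not np.all(np.diag(C) == 1):
            raise ShapeError("diagonal must be all ones (self-contacts)")
        if not np.isin(C, (0, 1)).all():
            raise ShapeError("contact matrix must be binary")
        self.C = C.astype(np.int8)


@dataclass
class IncidenceStructure:
    """Hypergraph G = (V, eps) as incidence matrix plus degrees.

    ``incidence`` is the N x K binary node-to-edge membership matrix,
    ``edges`` the corresponding node-index sets in column order.
    """

    incidence: np.ndarray  # (N, K)
    node_degrees: np.ndarray  # (N,)
    edge_degrees: np.ndarray  # (K,)
    edges: list[frozenset[int]]

    @property
    def n_nodes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    def validate(self) -> "IncidenceStructure":
        I = self.incidence
        if not np.array_equal(I.sum(axis=1), self.node_degrees):
            raise ShapeError("node degrees do not match incidence row sums")
        if not np.array_equal(I.sum(axis=0), self.edge_degrees):
            raise ShapeError("edge degrees do not match incidence column sums")
        if np.any(self.node_degrees < 1):
            raise ShapeError("every node must belong to at least one edge")
        if np.any(self.edge_degrees < 1):
            raise ShapeError("empty hyperedge")
        if max(self.edge_degrees, default=0) < 2:
            raise RecordRejected("no hyperedge with >= 2 members")
        cols = {tuple(I[:, k]) for k in range(self.n_edges)}
        if len(cols) != self.n_edges:
            raise ShapeError("duplicate incidence columns")
        return self

    def to_triplets(self, path: str | Path) -> None:
        """Debug serialization: one ``node<TAB>edge<TAB>1`` line per
        membership, in (edge, node) order."""
        lines = [
            f"{n}\t{k}\t1"
            for k in range(self.n_edges)
            for n in sorted(self.edges[k])
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def binarize_contacts(A: np.ndarray, ratio: float = 0.5) -> BinaryContacts:
    """Keep the top ``ceil(ratio * P)`` of the P = N(N-1)/2 off-diagonal
    pair scores (ties at the cut resolved by smallest (i, j), so the
    retained count is exact); the diagonal is forced to 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"contact map must be square, got {A.shape}")
    n = A.shape[0]
    if n < 2:
        raise TooShort("need at least 2 residues to build contacts")
    if not np.allclose(A, A.T, atol=1e-8):
        raise AsymmetricMap("contact map is not symmetric")
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keep = math.ceil(ratio * len(pairs))
    # descending score; ties broken toward smallest (i, j)
    order = sorted(pairs, key=lambda p: (-A[p], p[0], p[1]))
    C = np.eye(n, dtype=np.int8)
    for i, j in order[:keep]:
        C[i, j] = C[j, i] = 1
    return BinaryContacts(C)


def build_hyperedges(contacts: BinaryContacts) -> IncidenceStructure:
    """Rows of C as candidate hyperedges; dedup by set equality keeping
    the first occurrence; reject the record if every surviving edge is
    a singleton."""
    C = contacts.C
    n = C.shape[0]
    edges: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for i in range(n):
        edge = frozenset(np.flatnonzero(C[i]).tolist())
        if edge not in seen:
            seen.add(edge)
            edges.append(edge)
    if max(len(e) for e in edges) < 2:
        raise RecordRejected(
            "all hyperedges are self-loops; binding pair carries no structure"
        )
    K = len(edges)
    I = np.zeros((n, K), dtype=np.int8)
    for k, edge in enumerate(edges):
        I[sorted(edge), k] = 1
    return IncidenceStructure(
        incidence=I,
        node_degrees=I.sum(axis=1),
        edge_degrees=I.sum(axis=0),
        edges=edges,
    ).validate()


def hypergraph_from_contacts(A: np.ndarray, ratio: float = 0.5) -> IncidenceStructure:
    return build_hyperedges(binarize_contacts(A, ratio))


def hyperconv_twostep(X: np.ndarray, I: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Unnormalized node-edge-node composition ``I (I^T X Phi)``.

    Kept as the transparent two-stage form; the production operator
    :func:`hyperconv_forward` adds degree normalization.
    """
    X, I, Phi = np.asarray(X, float), np.asarray(I, float), np.asarray(Phi, float)
    if X.shape[0] != I.shape[0]:
        raise ShapeError(f"X rows {X.shape[0]} != incidence rows {I.shape[0]}")
    if Phi.shape[0] != X.shape[1]:
        raise ShapeError(f"Phi expects width {Phi.shape[0]}, X has {X.shape[1]}")
    M_E = I.T @ X @ Phi  # hyperedge aggregation
    return I @ M_E  # hypernode aggregation


def propagation_matrix(inc: IncidenceStructure) -> np.ndarray:
    """``D_v^{-1/2} I D_e^{-1} I^T D_v^{-1/2}`` — symmetric,
    non-negative, with eigenvector D_v^{1/2} 1 at eigenvalue 1."""
    I = inc.incidence.astype(float)
    dv = inc.node_degrees.astype(float)
    de = inc.edge_degrees.astype(float)
    Dv_isqrt = 1.0 / np.sqrt(dv)
    return (Dv_isqrt[:, None] * I) @ (I.T * (1.0 / de)[:, None]) * Dv_isqrt[None, :]


def hyperconv_forward(
    X: np.ndarray,
    inc: IncidenceStructure,
    Phi: np.ndarray,
    activation: str = "identity",
) -> np.ndarray:
    """One degree-normalized hypergraph convolution layer."""
    X = np.asarray(X, dtype=float)
    Phi = np.asarray(Phi, dtype=float)
    if X.shape[0] != inc.n_nodes:
        raise ShapeError(f"X rows {X.shape[0]} != nodes {inc.n_nodes}")
    if Phi.ndim != 2 or Phi.shape[0] != X.shape[1]:
        raise ShapeError(f"Phi shape {Phi.shape} incompatible with X width {X.shape[1]}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
    out = propagation_matrix(inc) @ X @ Phi
    return _ACTIVATIONS[activation](out)


__all__ = [
    "BinaryContacts",
    "IncidenceStructure",
    "binarize_contacts",
    "build_hyperedges",
    "hypergraph_from_contacts",
    "hyperconv_twostep",
    "hyperconv_forward",
    "propagation_matrix",
]
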