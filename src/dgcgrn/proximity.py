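"""Directed graphs and their first- / second-order proximity matrices.

A gene regulatory network is a weighted directed graph G=(V,E) with adjacency
A, A[i,j] the weight of the edge v_i -> v_j.  Three symmetric proximity
matrices summarise its structure for spectral convolution:

* first-order  A_F      = sym(A)                 (direct regulation),
* second-order A_S_in   (i,j) = sum_k A[k,i] A[k,j] / sum_v A[k,v]
                                                 (shared regulators),
* second-order A_S_out  (i,j) = sum_k A[i,k] A[j,k] / sum_v A[v,k]
                                                 (shared targets).

Each is then given a self-loop and symmetrically degree-normalised,
D^{-1/2} (M + I) D^{-1/2}, before entering the convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DirectedGRN",
    "ProximityMatrices",
    "first_order_proximity",
    "second_order_in",
    "second_order_out",
    "normalize_self_loop",
    "build_proximity",
]


@dataclass
class DirectedGRN:
    """Node set plus weighted directed adjacency matrix.

    ``A[i, j]`` is the weight of the directed edge node_ids[i] -> node_ids[j]
    (0 if absent).  Weights are nonnegative; the diagonal is zero on
    construction — self-loops enter only during normalisation.
    """

    node_ids: list[str]
    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.node_ids)
        if self.A.shape != (n, n):
            raise ValueError(f"adjacency shape {self.A.shape} != ({n}, {n})")
        if np.any(self.A < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("self-loops are not allowed on construction")

    @classmethod
    def from_edges(cls, node_ids: list[str],
                   edges: list[tuple[str, str]] | list[tuple[str, str, float]],
                   ) -> "DirectedGRN":
        """Build a graph from (source, target[, weight]) tuples; default weight 1."""
        index = {g: i for i, g in enumerate(node_ids)}
        A = np.zeros((len(node_ids), len(node_ids)))
        for e in edges:
            s, t = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            if s == t:
                continue  # self-regulation excluded from the message graph
            if s in index and t in index:
                A[index[s], index[t]] = w
        return cls(list(node_ids), A)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def edge_index(self) -> np.ndarray:
        """(m, 2) array of (source, target) index pairs, row-major order."""
        src, tgt = np.nonzero(self.A)
        return np.column_stack([src, tgt])

    def with_weights(self, weights: dict[tuple[int, int], float]) -> "DirectedGRN":
        """Return a copy with the same edge set but new edge weights."""
        A = self.A.copy()
        for (i, j), w in weights.items():
            if A[i, j] == 0:
                raise ValueError(f"({i}, {j}) is not an edge of the graph")
            A[i, j] = w
        return DirectedGRN(list(self.node_ids), A)


@dataclass
class ProximityMatrices:
    """The three proximity matrices and their normalised companions."""

    A_F: np.ndarray
    A_S_in: np.ndarray
    A_S_out: np.ndarray
    norm_F: np.ndarray = field(default=None)
    norm_S_in: np.ndarray = field(default=None)
    norm_S_out: np.ndarray = field(default=None)


def first_order_proximity(g: DirectedGRN, mode: str = "max") -> np.ndarray:
    """Symmetrised adjacency.

    ``mode`` resolves doubly-connected pairs with asymmetric weights:
    elementwise ``max`` (default; logical OR for binary graphs), ``sum`` or
    ``mean`` of the two directions.
    """
    A = g.A
    if mode == "max":
        return np.maximum(A, A.T)
    if mode == "sum":
        return A + A.T
    if mode == "mean":
        both = (A > 0) & (A.T > 0)
        out = A + A.T
        out[both] /= 2.0
        return out
    raise ValueError(f"unknown symmetrisation mode {mode!r}")


def second_order_in(g: DirectedGRN) -> np.ndarray:
    """Shared-regulator proximity: sum_k A[k,i] A[k,j] / sum_v A[k,v].

    Rows of A with zero sum (nodes with no out-edges) cannot mediate and are
    skipped, so entries are 0 exactly where i and j share no parent.
    """
    A = g.A
    rs = A.sum(axis=1)
    B = np.divide(A, rs[:, None], out=np.zeros_like(A), where=rs[:, None] > 0)
    S = B.T @ A
    return (S + S.T) / 2.0  # mathematically symmetric; enforce it exactly


def second_order_out(g: DirectedGRN) -> np.ndarray:
    """Shared-target proximity: sum_k A[i,k] A[j,k] / sum_v A[v,k]."""
    A = g.A
    cs = A.sum(axis=0)
    C = np.divide(A, cs[None, :], out=np.zeros_like(A), where=cs[None, :] > 0)
    S = C @ A.T
    return (S + S.T) / 2.0


def normalize_self_loop(M: np.ndarray) -> np.ndarray:
    """Symmetric degree normalisation with a self-loop.

    Returns ``D^{-1/2} (M + I) D^{-1/2}`` with D the diagonal of row sums of
    M + I.  Row sums are >= 1, so the result is always finite; its largest
    eigenvalue is 1 and its diagonal strictly positive.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T):
        raise ValueError("matrix must be symmetric")
    Mt = M + np.eye(M.shape[0])
    d = Mt.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    out = Mt * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (out + out.T) / 2.0  # remove last-ulp asymmetry of the scaling


def build_proximity(g: DirectedGRN, sym_mode: str = "max") -> ProximityMatrices:
    """Compute all three proximity matrices and their normalised forms."""
    A_F = first_order_proximity(g, mode=sym_mode)
    A_in = second_order_in(g)
    A_out = second_order_out(g)
    return ProximityMatrices(
        A_F=A_F, A_S_in=A_in, A_S_out=A_out,
        norm_F=normalize_self_loop(A_F),
        norm_S_in=normalize_self_loop(A_in),
        norm_S_out=normalize_self_loop(A_out),
    )
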