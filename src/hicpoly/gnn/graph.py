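"""Graph construction from 100 kb contact maps, and the signed-log
parameter transform used for the training loss."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import ContactMap, distance_normalize

__all__ = ["GraphInput", "build_graph", "signed_log_transform", "signed_log_inverse"]

N_NODE_EIGVECS = 10


@dataclass
class GraphInput:
    """GNN input: adjacency A (n x n), node features X (n x 10) and
    per-edge 2-vector features E (n x n x 2, defined where A = 1)."""

    adjacency: np.ndarray
    node_features: np.ndarray
    edge_features: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def build_graph(H100: ContactMap) -> GraphInput:
    """Build (A, X, E) from a 100 kb contact map.

    The map is first normalized by the mean of its main diagonal, then
    the diagonal is overwritten with 1.  ``A_ij = 1`` iff the entry is
    positive (strictly positive maps give a complete graph).  Node
    features are the top 10 eigenvectors (by eigenvalue magnitude) of the
    distance-normalized map; edge features are ``[log H_ij, mean of
    diagonal |i - j|]``.
    """
    vals = np.asarray(H100.values, dtype=float)
    if not np.any(vals > 0):
        raise ValueError("all-zero contact map")
    diag_mean = np.diag(vals).mean()
    if diag_mean > 0:
        vals = vals / diag_mean
    np.fill_diagonal(vals, 1.0)
    n = vals.shape[0]

    A = (vals > 0).astype(float)

    Hn = distance_normalize(
        ContactMap(vals, resolution_bp=H100.resolution_bp, chrom=H100.chrom,
                   start_bp=H100.start_bp, is_normalized=True)
    )
    evals, evecs = np.linalg.eigh(Hn.values)
    order = np.argsort(-np.abs(evals), kind="stable")[: min(N_NODE_EIGVECS, n)]
    X = evecs[:, order]
    if X.shape[1] < N_NODE_EIGVECS:  # tiny maps: pad with zero columns
        X = np.pad(X, ((0, 0), (0, N_NODE_EIGVECS - X.shape[1])))

    diag_means = np.array([np.diagonal(vals, offset=d).mean() for d in range(n)])
    i, j = np.indices((n, n))
    with np.errstate(divide="ignore"):
        logH = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), 0.0)
    E = np.stack([logH, diag_means[np.abs(i - j)]], axis=-1)
    E *= A[:, :, None]
    return GraphInput(adjacency=A, node_features=X, edge_features=E)


def signed_log_transform(U: np.ndarray) -> np.ndarray:
    """Elementwise ``sign(U) * ln(|U| + 1)``."""
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("non-finite input")
    return np.sign(U) * np.log1p(np.abs(U))


def signed_log_inverse(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`signed_log_transform`: ``sign(x) * (exp(|x|) - 1)``."""
    X = np.asarray(X, dtype=float)
    return np.sign(X) * np.expm1(np.abs(X))
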