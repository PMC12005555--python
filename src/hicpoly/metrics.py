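"""Contact-map and structure comparison metrics.

Implements the stratum-adjusted correlation coefficient (SCC), the
HiC-Spector Laplacian-eigenvector score, the PC1 Pearson correlation and
RMSE of distance-normalized maps, and the upper-triangle Pearson
correlation used for mean spatial distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.sparse.csgraph import connected_components

from .preprocess import ContactMap, NormalizedMap, compartment_pc1

__all__ = [
    "MetricReport",
    "scc",
    "hic_spector",
    "corr_pc1",
    "rmse_norm",
    "pearson_upper_triangle",
    "evaluate_pair",
]

SCC_H_DEFAULT = 5
SCC_K_DEFAULT = 100
SPECTOR_KAPPA_DEFAULT = 10


@dataclass
class MetricReport:
    """One row of comparison metrics for a pair of contact maps."""

    scc: float
    hic_spector: float
    corr_pc1: float
    rmse_norm: float
    h: int = SCC_H_DEFAULT
    K: int = SCC_K_DEFAULT
    kappa: int = SPECTOR_KAPPA_DEFAULT

    def to_tsv_row(self) -> str:
        header = "scc\thic_spector\tcorr_pc1\trmse_norm\th\tK\tkappa"
        row = (
            f"{self.scc:.6g}\t{self.hic_spector:.6g}\t{self.corr_pc1:.6g}\t"
            f"{self.rmse_norm:.6g}\t{self.h}\t{self.K}\t{self.kappa}"
        )
        return header + "\n" + row + "\n"


def _values(H) -> np.ndarray:
    return np.asarray(H.values if hasattr(H, "values") else H, dtype=float)


def _vstran(x: np.ndarray) -> np.ndarray:
    """Uniform quantile (rank) transform used for SCC weight stabilization."""
    n = len(x)
    ranks = np.empty(n)
    order = np.argsort(x, kind="stable")
    ranks[order] = np.arange(1, n + 1)
    return ranks / n


def scc(H1, H2, h: int = SCC_H_DEFAULT, K: int = SCC_K_DEFAULT) -> float:
    """Stratum-adjusted correlation coefficient.

    Both maps are first smoothed with a (2h+1) x (2h+1) mean filter; the
    Pearson correlation is computed per off-diagonal stratum d = 1..K and
    averaged with weights ``w_d = N_d * s1_d * s2_d`` where ``s`` are the
    standard deviations of the rank-transformed stratum values
    (variance-stabilized weighting).  Strata with zero variance in either
    map are skipped.
    """
    A = _values(H1)
    B = _values(H2)
    if A.shape != B.shape:
        raise ValueError("contact maps must have the same shape")
    m = A.shape[0]
    if K >= m:
        raise ValueError(f"K={K} must be smaller than map size m={m}")
    if h < 0:
        raise ValueError("smoothing half-width h must be >= 0")
    if h > 0:
        A = uniform_filter(A, size=2 * h + 1, mode="nearest")
        B = uniform_filter(B, size=2 * h + 1, mode="nearest")
    num = 0.0
    den = 0.0
    for d in range(1, K + 1):
        x = np.diagonal(A, offset=d)
        y = np.diagonal(B, offset=d)
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        w = len(x) * _vstran(x).std() * _vstran(y).std()
        num += w * r
        den += w
    if den == 0:
        warnings.warn("no informative strata; SCC undefined, returning NaN")
        return float("nan")
    return float(num / den)


def _laplacian_eigvecs(W: np.ndarray, kappa: int) -> np.ndarray:
    """Leading eigenvectors (smallest nontrivial eigenvalues) of the
    symmetric-normalized Laplacian, restricted to the largest connected
    component if the contact graph is disconnected."""
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    adj = (W > 0) & ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    keep = np.arange(m)
    if n_comp > 1:
        warnings.warn(
            f"contact graph has {n_comp} components; restricting to the largest"
        )
        largest = np.argmax(np.bincount(labels))
        keep = np.where(labels == largest)[0]
        W = W[np.ix_(keep, keep)]
    deg = W.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(W.shape[0]) - d_isqrt[:, None] * W * d_isqrt[None, :]
    lap = 0.5 * (lap + lap.T)
    evals, evecs = np.linalg.eigh(lap)
    # skip the trivial (near-zero) eigenvector, take the next kappa
    vecs = evecs[:, 1 : 1 + kappa]
    full = np.zeros((m, vecs.shape[1]))
    full[keep] = vecs
    return full


def hic_spector(H1, H2, kappa: int = SPECTOR_KAPPA_DEFAULT) -> float:
    """HiC-Spector reproducibility score in [0, 1] (higher is better).

    Compares the leading ``kappa`` eigenvectors of the symmetric-normalized
    graph Laplacians of the two maps.  Each eigenvector pair is sign-aligned
    to minimize Euclidean distance; the score is
    ``1 - (1/kappa) * sum ||v_i - u_i|| / sqrt(2)``.
    """
    A = _values(H1)
    B = _values(H2)
    if A.shape != B.shape:
        raise ValueError("contact maps must have the same shape")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    V = _laplacian_eigvecs(A, kappa)
    Uv = _laplacian_eigvecs(B, kappa)
    k = min(V.shape[1], Uv.shape[1])
    dists = 0.0
    for i in range(k):
        d_plus = np.linalg.norm(V[:, i] - Uv[:, i])
        d_minus = np.linalg.norm(V[:, i] + Uv[:, i])
        dists += min(d_plus, d_minus)
    score = 1.0 - dists / (k * np.sqrt(2.0))
    return float(min(max(score, 0.0), 1.0))


def corr_pc1(Hn1, Hn2) -> float:
    """Pearson correlation between the two maps' compartment PC1 vectors.

    PC1 sign is arbitrary, so one vector's sign is flipped whenever that
    increases the magnitude of the correlation.
    """
    p1 = compartment_pc1(Hn1)
    p2 = compartment_pc1(Hn2)
    if np.allclose(p1, 0) or np.allclose(p2, 0) or p1.std() == 0 or p2.std() == 0:
        warnings.warn("degenerate PC1; correlation undefined, returning NaN")
        return float("nan")
    r = float(np.corrcoef(p1, p2)[0, 1])
    # flipping one PC1's sign maps r -> -r, so the sign-aligned value is |r|
    return abs(r)


def rmse_norm(Hn1, Hn2) -> float:
    """Root-mean-squared error between two maps over all entries."""
    A = _values(Hn1)
    B = _values(Hn2)
    if A.shape != B.shape:
        raise ValueError("maps must have the same shape")
    return float(np.sqrt(np.mean((A - B) ** 2)))


def pearson_upper_triangle(D1: np.ndarray, D2: np.ndarray) -> float:
    """Pearson correlation over strict upper-triangle entries."""
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    if D1.shape != D2.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(D1.shape[0], k=1)
    x, y = D1[iu], D2[iu]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant matrix; correlation undefined, returning NaN")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_pair(
    H1: ContactMap,
    H2: ContactMap,
    Hn1: NormalizedMap,
    Hn2: NormalizedMap,
    h: int = SCC_H_DEFAULT,
    K: int = SCC_K_DEFAULT,
    kappa: int = SPECTOR_KAPPA_DEFAULT,
) -> MetricReport:
    """All four comparison metrics for a simulated/experimental map pair."""
    K_eff = min(K, H1.m - 1)
    return MetricReport(
        scc=scc(H1, H2, h=h, K=K_eff),
        hic_spector=hic_spector(H1, H2, kappa=kappa),
        corr_pc1=corr_pc1(Hn1, Hn2),
        rmse_norm=rmse_norm(Hn1, Hn2),
        h=h,
        K=K_eff,
        kappa=kappa,
    )
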