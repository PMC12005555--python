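"""Synthetic interaction-parameter and contact-map generation.

Builds pools of (L, T) parameter matrices — either loaded from real
maximum-entropy fits or generated as seeded fixtures — and samples new
parameter sets by drawing eigenvalues from per-rank kernel density
estimates over the pool's L spectra, reusing pool eigenvectors, and
reusing pool T matrices unchanged.  Simulating each sampled U yields
(contact map, parameters) training pairs for the neural network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde

from .simulator import (
    InteractionParams,
    PolymerConfig,
    contact_map_from_ensemble,
    sample_ensemble,
    toeplitz_from_diagonals,
)
from .preprocess import ContactMap

__all__ = [
    "ParameterPool",
    "EigenvalueKDE",
    "TrainingPair",
    "build_fixture_pool",
    "fit_eigenvalue_kde",
    "sample_L",
    "sample_T",
    "build_dataset",
]

DEFAULT_K = 10
_LABEL_CORR_LENGTH = 20  # bins; smoothing scale of fixture label tracks


@dataclass
class ParameterPool:
    """Pool of (L, T) interaction matrices sharing m and k."""

    L_pool: list[np.ndarray]
    T_pool: list[np.ndarray]
    provenance: str = "fixture"  # or "me_fits"
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.L_pool or not self.T_pool:
            raise ValueError("parameter pools must be non-empty")
        m = self.L_pool[0].shape[0]
        for L in self.L_pool:
            if L.shape != (m, m):
                raise ValueError("all pool members must share m")
        for T in self.T_pool:
            if T.shape != (m, m):
                raise ValueError("all pool members must share m")

    @property
    def m(self) -> int:
        return self.L_pool[0].shape[0]


@dataclass
class EigenvalueKDE:
    """Per-rank Gaussian KDEs over the pool's L eigenvalues.

    Rank r holds the density of the r-th eigenvalue (sorted by descending
    magnitude) across pool members.
    """

    kdes: list
    bandwidth: float | str = "silverman"

    @property
    def k(self) -> int:
        return len(self.kdes)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One eigenvalue per rank."""
        out = np.empty(self.k)
        for r, kde in enumerate(self.kdes):
            if callable(getattr(kde, "resample", None)):
                out[r] = kde.resample(1, seed=rng)[0, 0]
            else:  # degenerate rank: stored as (value, bandwidth)
                mu, bw = kde
                out[r] = mu + bw * rng.standard_normal()
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("KDE produced non-finite eigenvalue")
        return out


@dataclass
class TrainingPair:
    """A simulated contact map and the parameters that generated it."""

    H: ContactMap
    params: InteractionParams
    seed: int = 0

    @property
    def U(self) -> np.ndarray:
        return self.params.U


def _smoothed_walk(m: int, rng: np.random.Generator, corr_length: int) -> np.ndarray:
    """Random walk smoothed with a boxcar to give ~corr_length-bin features."""
    steps = rng.standard_normal(m)
    walk = np.cumsum(steps)
    kernel = np.ones(corr_length) / corr_length
    smooth = np.convolve(walk, kernel, mode="same")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    return smooth / (peak if peak > 0 else 1.0)


def build_fixture_pool(
    m: int, k: int = DEFAULT_K, n_members: int = 8, seed: int = 0
) -> ParameterPool:
    """Seeded stand-in pool emulating a set of maximum-entropy fits.

    Each member: label tracks Psi from smoothed random walks
    (correlation length ~20 bins), chi with Uniform(-1, 1) entries
    symmetrized, ``L = Psi chi Psi^T`` rescaled to unit max magnitude,
    and T diagonals ``t_d = -c (1 + d)^(-alpha)`` with c ~ U(0.3, 1) and
    alpha ~ U(0.7, 1.3).
    """
    if m < 1 or k < 1 or n_members < 1:
        raise ValueError("m, k and n_members must all be >= 1")
    rng = np.random.default_rng(seed)
    L_pool: list[np.ndarray] = []
    T_pool: list[np.ndarray] = []
    corr = min(_LABEL_CORR_LENGTH, max(2, m // 4))
    for _ in range(n_members):
        Psi = np.column_stack([_smoothed_walk(m, rng, corr) for _ in range(k)])
        chi = rng.uniform(-1.0, 1.0, size=(k, k))
        chi = 0.5 * (chi + chi.T)
        L = Psi @ chi @ Psi.T
        L = 0.5 * (L + L.T)
        peak = np.abs(L).max()
        if peak > 0:
            L = L / peak
        c = rng.uniform(0.3, 1.0)
        alpha = rng.uniform(0.7, 1.3)
        t_diag = -c * (1.0 + np.arange(m)) ** (-alpha)
        L_pool.append(L)
        T_pool.append(toeplitz_from_diagonals(t_diag))
    return ParameterPool(L_pool=L_pool, T_pool=T_pool, provenance="fixture", k=k)


def _top_eigh(L: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs by eigenvalue magnitude, deterministic sign
    convention (largest-magnitude component of each vector positive)."""
    evals, evecs = np.linalg.eigh(L)
    order = np.argsort(-np.abs(evals), kind="stable")[:k]
    vals = evals[order]
    vecs = evecs[:, order]
    for c in range(vecs.shape[1]):
        peak = np.argmax(np.abs(vecs[:, c]))
        if vecs[peak, c] < 0:
            vecs[:, c] = -vecs[:, c]
    return vals, vecs


def fit_eigenvalue_kde(pool: ParameterPool, bandwidth: float | str = "silverman") -> EigenvalueKDE:
    """Per-rank Gaussian KDEs over the pool members' top-k L eigenvalues."""
    spectra = np.array([_top_eigh(L, pool.k)[0] for L in pool.L_pool])  # (n_members, k)
    kdes = []
    for r in range(pool.k):
        vals = spectra[:, r]
        spread = vals.std()
        if len(vals) < 2 or spread < 1e-12:
            # degenerate rank: KDE bandwidth undefined; fall back to a
            # small fixed-width Gaussian around the observed value
            fallback_bw = max(1e-3, 1e-2 * abs(vals.mean()))
            kdes.append((float(vals.mean()), fallback_bw))
        else:
            kdes.append(gaussian_kde(vals, bw_method=bandwidth))
    return EigenvalueKDE(kdes=kdes, bandwidth=bandwidth)


def sample_L(kde: EigenvalueKDE, pool: ParameterPool, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a rank-<=k symmetric L: KDE eigenvalues in the eigenspace of
    a uniformly chosen pool member."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if kde.k != pool.k:
        raise ValueError("KDE and pool have inconsistent k")
    lam = kde.sample(rng)
    member = pool.L_pool[int(rng.integers(len(pool.L_pool)))]
    _, vecs = _top_eigh(member, pool.k)
    L = (vecs * lam) @ vecs.T
    return 0.5 * (L + L.T)


def sample_T(pool: ParameterPool, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """A uniformly chosen pool T matrix, returned unchanged."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    return pool.T_pool[int(rng.integers(len(pool.T_pool)))].copy()


def build_dataset(
    pool: ParameterPool,
    n_samples: int,
    poly_cfg: PolymerConfig,
    seed: int = 0,
) -> list[TrainingPair]:
    """Sample n parameter sets and simulate their contact maps.

    A pure function of (pool, n_samples, poly_cfg, seed): each sample
    draws ``U = sample_L + sample_T`` and runs the polymer model with a
    per-sample simulation seed derived from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if pool.m != poly_cfg.m:
        raise ValueError("pool m does not match polymer config m")
    rng = np.random.default_rng(seed)
    kde = fit_eigenvalue_kde(pool)
    pairs: list[TrainingPair] = []
    for s in range(n_samples):
        L = sample_L(kde, pool, rng)
        T = sample_T(pool, rng)
        params = InteractionParams(L, T)
        sim_seed = int(rng.integers(2**31 - 1))
        cfg = replace(poly_cfg, seed=sim_seed)
        ensemble = sample_ensemble(params, cfg)
        H = contact_map_from_ensemble(ensemble)
        pairs.append(TrainingPair(H=H, params=params, seed=sim_seed))
    return pairs


def save_dataset(pairs: list[TrainingPair], directory: str | Path) -> None:
    """Chunked archive: one .npz per pair plus a manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["sample\tseed\tm\tfile"]
    for s, pair in enumerate(pairs):
        fname = f"pair_{s:05d}.npz"
        np.savez_compressed(
            directory / fname,
            H=pair.H.values.astype(np.float32),
            L=pair.params.L.astype(np.float32),
            T=pair.params.T.astype(np.float32),
            seed=pair.seed,
        )
        lines.append(f"{s}\t{pair.seed}\t{pair.H.m}\t{fname}")
    (directory / "manifest.tsv").write_text("\n".join(lines) + "\n")


def load_dataset(directory: str | Path) -> list[TrainingPair]:
    directory = Path(directory)
    manifest = (directory / "manifest.tsv").read_text().strip().splitlines()[1:]
    pairs = []
    for line in manifest:
        _, seed, _, fname = line.split("\t")
        with np.load(directory / fname) as z:
            H = ContactMap(np.asarray(z["H"], dtype=float), is_normalized=True)
            params = InteractionParams(np.asarray(z["L"], dtype=float), np.asarray(z["T"], dtype=float))
        pairs.append(TrainingPair(H=H, params=params, seed=int(seed)))
    return pairs
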