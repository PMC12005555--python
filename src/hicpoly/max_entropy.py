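"""Iterative maximum-entropy fitting of interaction parameters.

Adjusts the type-type interaction matrix chi (parameterizing the
low-rank term ``L = Psi chi Psi^T``) and the per-distance Toeplitz
values ``t_d`` until the simulated contact map reproduces a target map's
observables: type-type co-contact sums and per-diagonal contact means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ContactMap, compartment_pc1, distance_normalize
from .simulator import (
    InteractionParams,
    PolymerConfig,
    contact_map_from_ensemble,
    sample_ensemble,
)

__all__ = [
    "LabelTracks",
    "ChiMatrix",
    "MEState",
    "default_labels",
    "compute_observables",
    "me_update",
    "me_fit",
]

DEFAULT_K = 10


@dataclass
class LabelTracks:
    """Per-bead particle labels Psi (m x k)."""

    Psi: np.ndarray

    def __post_init__(self) -> None:
        self.Psi = np.atleast_2d(np.asarray(self.Psi, dtype=float))
        if not np.all(np.isfinite(self.Psi)):
            raise ValueError("labels must be finite")
        if self.Psi.shape[1] < 1:
            raise ValueError("need at least one label track")

    @property
    def m(self) -> int:
        return self.Psi.shape[0]

    @property
    def k(self) -> int:
        return self.Psi.shape[1]


@dataclass
class ChiMatrix:
    """Symmetric k x k type-type interaction strengths."""

    chi: np.ndarray

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.chi = 0.5 * (self.chi + self.chi.T)

    @property
    def k(self) -> int:
        return self.chi.shape[0]


@dataclass
class MEState:
    """Iteration history of the maximum-entropy optimization."""

    iteration: int
    chi: ChiMatrix
    t_diag: np.ndarray
    observable_residuals: list[float] = field(default_factory=list)
    converged: bool = False
    epsilon: float = 1e-2

    def __post_init__(self) -> None:
        if len(self.observable_residuals) != self.iteration:
            raise ValueError("residual history length must equal iteration count")


def default_labels(H_target: ContactMap, k: int = DEFAULT_K) -> LabelTracks:
    """Top-k principal-component score vectors of the distance-normalized
    target map, each rescaled to unit max magnitude."""
    Hn = distance_normalize(H_target)
    vals = Hn.values - Hn.values.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(vals, full_matrices=False)
    k = min(k, vt.shape[0])
    Psi = (vt[:k] * s[:k, None]).T
    scale = np.abs(Psi).max(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return LabelTracks(Psi / scale)


def compute_observables(H: ContactMap, Psi: LabelTracks) -> tuple[np.ndarray, np.ndarray]:
    """Type-type co-contact sums and per-distance contact means.

    ``f_ab = sum_{i<j} (Psi_ia Psi_jb + Psi_ib Psi_ja) H_ij`` (equal to
    ``Psi^T H0 Psi`` with the diagonal of H zeroed) and ``g_d`` the mean
    of H over diagonal d.
    """
    vals = np.asarray(H.values, dtype=float)
    if Psi.m != vals.shape[0]:
        raise ValueError(f"labels m={Psi.m} do not match map m={vals.shape[0]}")
    H0 = vals.copy()
    np.fill_diagonal(H0, 0.0)
    f = Psi.Psi.T @ H0 @ Psi.Psi
    f = 0.5 * (f + f.T)
    g = np.array([np.diagonal(vals, offset=d).mean() for d in range(vals.shape[0])])
    return f, g


def me_update(
    state: MEState,
    sim_obs: tuple[np.ndarray, np.ndarray],
    target_obs: tuple[np.ndarray, np.ndarray],
    learning_rate: float,
    learning_rate_t: float | None = None,
) -> MEState:
    """One gradient-style update of (chi, t_diag).

    A simulated contact excess raises the corresponding parameter (more
    repulsive); the recorded residual is the max relative parameter
    change.
    """
    f_sim, g_sim = sim_obs
    f_tgt, g_tgt = target_obs
    eta_t = learning_rate if learning_rate_t is None else learning_rate_t
    d_chi = learning_rate * (f_sim - f_tgt)
    d_t = eta_t * (g_sim - g_tgt)
    if not (np.all(np.isfinite(d_chi)) and np.all(np.isfinite(d_t))):
        raise FloatingPointError("non-finite maximum-entropy update")
    new_chi = state.chi.chi + d_chi
    new_t = state.t_diag + d_t
    rel = np.concatenate(
        [
            (np.abs(d_chi) / (np.abs(new_chi) + 1e-8)).ravel(),
            np.abs(d_t) / (np.abs(new_t) + 1e-8),
        ]
    )
    residual = float(rel.max()) if rel.size else 0.0
    return MEState(
        iteration=state.iteration + 1,
        chi=ChiMatrix(new_chi),
        t_diag=new_t,
        observable_residuals=state.observable_residuals + [residual],
        converged=False,
        epsilon=state.epsilon,
    )


def me_fit(
    H_target: ContactMap,
    Psi: LabelTracks | None,
    epsilon: float,
    poly_cfg: PolymerConfig,
    max_iter: int = 20,
    learning_rate: float = 1.0,
    learning_rate_t: float | None = None,
    n_structures_opt: int = 5000,
    damping: float = 0.5,
) -> tuple[InteractionParams, MEState]:
    """Fit (chi, t_diag) so the simulated map reproduces the target.

    Each iteration simulates with the current parameters at a reduced
    sampling effort (``n_structures_opt``), compares observables and
    applies :func:`me_update`; iteration stops when the max relative
    parameter change drops below ``epsilon`` or after ``max_iter``
    iterations.  Non-convergence is reported via ``state.converged``,
    not an exception.  When the residual increases the learning rate is
    multiplied by ``damping``.
    """
    if Psi is None:
        Psi = default_labels(H_target)
    if Psi.m != H_target.m:
        raise ValueError("labels do not match target map size")
    if H_target.m != poly_cfg.m:
        raise ValueError("polymer config m does not match target map")
    target_obs = compute_observables(H_target, Psi)
    state = MEState(
        iteration=0,
        chi=ChiMatrix(np.zeros((Psi.k, Psi.k))),
        t_diag=np.zeros(H_target.m),
        epsilon=epsilon,
    )
    eta = learning_rate
    from dataclasses import replace

    for it in range(max_iter):
        params = InteractionParams.from_chi(Psi.Psi, state.chi.chi, state.t_diag)
        cfg = replace(
            poly_cfg,
            n_structures=min(n_structures_opt, poly_cfg.n_structures),
            seed=poly_cfg.seed + 1000 * it,
        )
        ensemble = sample_ensemble(params, cfg)
        H_sim = contact_map_from_ensemble(ensemble)
        sim_obs = compute_observables(H_sim, Psi)
        state = me_update(state, sim_obs, target_obs, eta, None if learning_rate_t is None else eta * learning_rate_t / learning_rate)
        res = state.observable_residuals
        if len(res) >= 2 and res[-1] > res[-2]:
            eta *= damping
        if res[-1] < epsilon:
            state.converged = True
            break
    if not state.converged and max_iter > 0:
        warnings.warn(
            f"maximum-entropy fit did not reach epsilon={epsilon} in {max_iter} iterations"
        )
    params = InteractionParams.from_chi(Psi.Psi, state.chi.chi, state.t_diag)
    return params, state
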