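"""Grid-based heteropolymer Monte Carlo simulator.

Samples chromatin structures under a Gaussian-chain bonded potential
plus a grid co-occupancy pair potential parameterized by an interaction
matrix ``U = L + T`` (low-rank type-type term plus Toeplitz
genomic-distance term).  Contact maps are ensemble averages of the
same-cell indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import toeplitz

from . import _mc
from .preprocess import ContactMap

__all__ = [
    "PolymerConfig",
    "InteractionParams",
    "StructureEnsemble",
    "GridAssignment",
    "bonded_energy",
    "assign_grid",
    "nonbonded_energy",
    "sample_ensemble",
    "contact_map_from_ensemble",
    "mean_distance_matrix",
    "toeplitz_from_diagonals",
]


@dataclass
class PolymerConfig:
    """Simulation settings.

    Default bond length is 200 nm and default confinement volume 8 um^3
    (a 2 um hard-wall cube).  The contact grid cell defaults to the bond
    length.  Move mix is single-bead displacement / crankshaft rotation /
    whole-chain translation.
    """

    m: int = 512
    bond_length_nm: float = 200.0
    volume_um3: float = 8.0
    grid_cell_nm: float | None = None
    n_structures: int = 30_000
    n_equilibration_sweeps: int = 1000
    n_sweeps_between_samples: int = 10
    seed: int = 0
    move_weights: tuple[float, float, float] = (0.8, 0.15, 0.05)
    bead_step_nm: float | None = None
    crank_max_seg: int = 8
    debug_energy_every: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 beads")
        if self.bond_length_nm <= 0 or self.volume_um3 <= 0:
            raise ValueError("bond length and volume must be positive")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.grid_cell_nm is None:
            self.grid_cell_nm = self.bond_length_nm
        if self.grid_cell_nm <= 0:
            raise ValueError("grid cell must be positive")
        if self.bead_step_nm is None:
            # ~40% acceptance for a free Gaussian chain at b = cell
            self.bead_step_nm = 0.75 * self.bond_length_nm
        w = np.asarray(self.move_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("move weights must be nonnegative and not all zero")
        self.move_weights = tuple(w / w.sum())

    @property
    def box_nm(self) -> float:
        return (self.volume_um3 * 1e9) ** (1.0 / 3.0)


@dataclass
class InteractionParams:
    """Interaction matrices: ``U = L + T``.

    ``L`` is symmetric (low-rank by construction when produced by the
    generator or the maximum-entropy fit) and ``T`` is symmetric Toeplitz.
    """

    L: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.L.shape != self.T.shape or self.L.ndim != 2 or self.L.shape[0] != self.L.shape[1]:
            raise ValueError("L and T must be square matrices of the same shape")
        if not np.allclose(self.L, self.L.T, atol=1e-9):
            raise ValueError("L must be symmetric")
        if not np.allclose(self.T, self.T.T, atol=1e-9):
            raise ValueError("T must be symmetric")
        m = self.T.shape[0]
        first = self.T[0]
        expect = toeplitz(first)
        if not np.allclose(self.T, expect, atol=1e-9):
            raise ValueError("T must be Toeplitz (constant descending diagonals)")

    @property
    def U(self) -> np.ndarray:
        return self.L + self.T

    @property
    def m(self) -> int:
        return self.L.shape[0]

    @classmethod
    def zeros(cls, m: int) -> "InteractionParams":
        return cls(np.zeros((m, m)), np.zeros((m, m)))

    @classmethod
    def from_chi(cls, Psi: np.ndarray, chi: np.ndarray, t_diag: np.ndarray) -> "InteractionParams":
        """Build ``L = Psi chi Psi^T`` and ``T`` from per-distance values."""
        Psi = np.asarray(Psi, dtype=float)
        chi = np.asarray(chi, dtype=float)
        chi = 0.5 * (chi + chi.T)
        L = Psi @ chi @ Psi.T
        L = 0.5 * (L + L.T)
        return cls(L, toeplitz_from_diagonals(np.asarray(t_diag, dtype=float)))


def toeplitz_from_diagonals(t_diag: np.ndarray) -> np.ndarray:
    """Symmetric Toeplitz matrix whose d-th diagonal is ``t_diag[d]``."""
    return toeplitz(np.asarray(t_diag, dtype=float))


@dataclass
class GridAssignment:
    """Per-bead grid cell index under an offset grid."""

    cells: np.ndarray  # (m, 3) integer cell triples
    grid_cell_nm: float
    offset: np.ndarray

    def indicator(self) -> np.ndarray:
        """Same-cell indicator matrix I (symmetric, unit diagonal)."""
        same = np.all(self.cells[:, None, :] == self.cells[None, :, :], axis=2)
        return same.astype(float)


@dataclass
class StructureEnsemble:
    """Sampled structures (nm) plus the grid offsets in effect at sampling."""

    coords: np.ndarray  # (n_structures, m, 3)
    offsets: np.ndarray  # (n_structures, 3)
    config: PolymerConfig

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            coords=self.coords.astype(np.float32),
            offsets=self.offsets,
            m=self.config.m,
            seed=self.config.seed,
            bond_length_nm=self.config.bond_length_nm,
            volume_um3=self.config.volume_um3,
            grid_cell_nm=self.config.grid_cell_nm,
        )

    def to_xyz(self, path: str | Path, max_frames: int | None = None) -> None:
        """Export structures as multi-frame XYZ (one model per frame)."""
        n = self.n_structures if max_frames is None else min(max_frames, self.n_structures)
        with open(path, "w") as fh:
            for s in range(n):
                fh.write(f"{self.m}\nframe {s}\n")
                for i in range(self.m):
                    x, y, z = self.coords[s, i]
                    fh.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")


# ---------------------------------------------------------------------------
# Energies


def bonded_energy(coords: np.ndarray, b: float) -> float:
    """Gaussian-chain bonded energy (kT): (3 / 2 b^2) sum |r_{i+1} - r_i|^2."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diffs = np.diff(coords, axis=0)
    return float(1.5 / (b * b) * np.sum(diffs * diffs))


def assign_grid(coords: np.ndarray, grid_cell_nm: float, offset: np.ndarray) -> GridAssignment:
    """Assign beads to grid cells: floor((r + offset) / cell) per axis."""
    coords = np.asarray(coords, dtype=float)
    offset = np.asarray(offset, dtype=float)
    cells = np.floor((coords + offset[None, :]) / grid_cell_nm).astype(np.int64)
    return GridAssignment(cells=cells, grid_cell_nm=grid_cell_nm, offset=offset)


def nonbonded_energy(assignment: GridAssignment, U: np.ndarray) -> float:
    """Sum of U_ij over unordered co-celled pairs i < j (self-pairs excluded)."""
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("non-finite interaction matrix")
    I = assignment.indicator()
    iu = np.triu_indices(U.shape[0], k=1)
    return float(np.sum(I[iu] * U[iu]))


# ---------------------------------------------------------------------------
# Sampling


def _initial_coords(cfg: PolymerConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-chain random walk started at the box center, clipped to the box.

    For U = 0 and a non-binding box this is an exact equilibrium draw,
    which keeps the equilibration burden low.
    """
    b = cfg.bond_length_nm
    steps = rng.normal(scale=b / np.sqrt(3.0), size=(cfg.m - 1, 3))
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    coords += cfg.box_nm / 2.0
    eps = 1e-6 * cfg.box_nm
    return np.clip(coords, eps, cfg.box_nm - eps)


def sample_ensemble(params: InteractionParams, config: PolymerConfig) -> StructureEnsemble:
    """Metropolis Monte Carlo sampling of the heteropolymer.

    Fully reproducible given ``config.seed``.  The grid origin is
    re-randomized before every sweep; each recorded sample stores the
    offset in effect so contact maps can be evaluated consistently.
    """
    if params.m != config.m:
        raise ValueError(f"params m={params.m} does not match config m={config.m}")
    U = np.ascontiguousarray(params.U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("non-finite interaction matrix")
    rng = np.random.default_rng(config.seed)
    coords = _initial_coords(config, rng)
    p_bead, p_crank, _ = config.move_weights
    samples, offsets, n_acc, n_moves, drift = _mc.run_mc(
        coords,
        U,
        config.bond_length_nm,
        config.box_nm,
        config.grid_cell_nm,
        config.n_structures,
        config.n_equilibration_sweeps,
        config.n_sweeps_between_samples,
        p_bead,
        p_crank,
        config.bead_step_nm,
        0.5 * config.grid_cell_nm,
        config.crank_max_seg,
        config.debug_energy_every,
        rng,
    )
    if not np.all(np.isfinite(samples)):
        raise FloatingPointError("divergent (non-finite) coordinates during sampling")
    if config.debug_energy_every > 0 and drift > 1e-6:
        raise AssertionError(
            f"incremental nonbonded energy drifted by {drift:.3g} kT from full recomputation"
        )
    return StructureEnsemble(coords=samples, offsets=offsets, config=config)


def contact_map_from_ensemble(ensemble: StructureEnsemble) -> ContactMap:
    """H_sim: fraction of structures in which each pair shares a grid cell.

    Each structure is evaluated with its own sampling-time grid offset.
    The main diagonal is 1 by definition (a bead always co-cells with
    itself).
    """
    if ensemble.n_structures < 1:
        raise ValueError("empty ensemble")
    counts = _mc.contact_counts(
        np.ascontiguousarray(ensemble.coords, dtype=float),
        np.ascontiguousarray(ensemble.offsets, dtype=float),
        ensemble.config.grid_cell_nm,
    )
    H = counts / float(ensemble.n_structures)
    np.fill_diagonal(H, 1.0)
    return ContactMap(H, resolution_bp=50_000, is_normalized=True)


def mean_distance_matrix(ensemble: StructureEnsemble) -> np.ndarray:
    """Ensemble-mean pairwise Euclidean distance matrix (nm)."""
    if ensemble.n_structures < 1:
        raise ValueError("empty ensemble")
    coords = ensemble.coords
    m = ensemble.m
    out = np.zeros((m, m))
    # chunk over structures to bound memory at large n
    chunk = max(1, int(2e7 // (m * m)))
    for lo in range(0, coords.shape[0], chunk):
        block = coords[lo : lo + chunk]
        d = np.linalg.norm(block[:, :, None, :] - block[:, None, :, :], axis=-1)
        out += d.sum(axis=0)
    return out / coords.shape[0]
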