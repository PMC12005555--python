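"""Numba kernels for grid-based heteropolymer Monte Carlo sampling.

Energy model: Gaussian-chain bonds plus a grid co-occupancy pair
potential.  Two beads interact with energy ``U[i, j]`` (kT) when they
fall in the same cell of a uniform grid whose origin offset is
re-randomized before every sweep.  Confinement is a hard-wall cube.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# move-type codes
_BEAD, _CRANK, _TRANS = 0, 1, 2


@njit(cache=True)
def _cell_of(x, y, z, cell, off):
    return (
        np.int64(np.floor((x + off[0]) / cell)),
        np.int64(np.floor((y + off[1]) / cell)),
        np.int64(np.floor((z + off[2]) / cell)),
    )


@njit(cache=True)
def _assign_cells(coords, cell, off, cells):
    m = coords.shape[0]
    for i in range(m):
        cx, cy, cz = _cell_of(coords[i, 0], coords[i, 1], coords[i, 2], cell, off)
        cells[i, 0] = cx
        cells[i, 1] = cy
        cells[i, 2] = cz


@njit(cache=True)
def _same_cell(cells, i, j):
    return (
        cells[i, 0] == cells[j, 0]
        and cells[i, 1] == cells[j, 1]
        and cells[i, 2] == cells[j, 2]
    )


@njit(cache=True)
def bonded_energy_nb(coords, b):
    m = coords.shape[0]
    e = 0.0
    for i in range(m - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        e += dx * dx + dy * dy + dz * dz
    return 1.5 / (b * b) * e


@njit(cache=True)
def nonbonded_energy_nb(cells, U):
    m = cells.shape[0]
    e = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            if _same_cell(cells, i, j):
                e += U[i, j]
    return e


@njit(cache=True)
def _pair_energy_of_bead(cells, U, i):
    """Nonbonded energy of all pairs involving bead i."""
    m = cells.shape[0]
    e = 0.0
    for j in range(m):
        if j != i and _same_cell(cells, i, j):
            e += U[i, j]
    return e


@njit(cache=True)
def _segment_energy(cells, U, lo, hi):
    """Nonbonded energy of all pairs with at least one bead in [lo, hi)."""
    m = cells.shape[0]
    e = 0.0
    for a in range(lo, hi):
        for j in range(m):
            if j < lo or j >= hi:
                if _same_cell(cells, a, j):
                    e += U[a, j]
            elif j > a:
                if _same_cell(cells, a, j):
                    e += U[a, j]
    return e


@njit(cache=True)
def _in_box(x, y, z, box):
    return 0.0 <= x <= box and 0.0 <= y <= box and 0.0 <= z <= box


@njit(cache=True)
def _rotate_about_axis(p, a0, axis, cos_t, sin_t):
    """Rodrigues rotation of point p about a line through a0 with unit axis."""
    vx = p[0] - a0[0]
    vy = p[1] - a0[1]
    vz = p[2] - a0[2]
    dot = vx * axis[0] + vy * axis[1] + vz * axis[2]
    cx = axis[1] * vz - axis[2] * vy
    cy = axis[2] * vx - axis[0] * vz
    cz = axis[0] * vy - axis[1] * vx
    rx = vx * cos_t + cx * sin_t + axis[0] * dot * (1.0 - cos_t)
    ry = vy * cos_t + cy * sin_t + axis[1] * dot * (1.0 - cos_t)
    rz = vz * cos_t + cz * sin_t + axis[2] * dot * (1.0 - cos_t)
    return a0[0] + rx, a0[1] + ry, a0[2] + rz


@njit(cache=True)
def run_mc(
    coords,
    U,
    b,
    box,
    cell,
    n_samples,
    equil_sweeps,
    sweeps_between,
    p_bead,
    p_crank,
    bead_step,
    trans_step,
    crank_max_seg,
    debug_every,
    rng,
):
    """Metropolis MC; returns (samples, offsets, n_accepted, n_moves, max_drift).

    ``samples`` is (n_samples, m, 3); ``offsets`` holds the grid offset in
    effect when each sample was recorded.  When ``debug_every > 0`` the
    incrementally tracked nonbonded energy is compared against a full
    recomputation every ``debug_every`` moves and the maximum discrepancy
    is returned as ``max_drift``.
    """
    m = coords.shape[0]
    cells = np.empty((m, 3), dtype=np.int64)
    off = np.empty(3)
    for a in range(3):
        off[a] = rng.random() * cell
    _assign_cells(coords, cell, off, cells)
    e_nb = nonbonded_energy_nb(cells, U)

    samples = np.empty((n_samples, m, 3))
    offsets = np.empty((n_samples, 3))
    new_seg = np.empty((m, 3))
    n_acc = 0
    n_moves = 0
    max_drift = 0.0
    total_sweeps = equil_sweeps + n_samples * sweeps_between
    n_recorded = 0

    for sweep in range(total_sweeps):
        # re-randomize grid origin: recompute assignment and energy
        for a in range(3):
            off[a] = rng.random() * cell
        _assign_cells(coords, cell, off, cells)
        e_nb = nonbonded_energy_nb(cells, U)

        for _ in range(m):
            n_moves += 1
            u = rng.random()
            if u < p_bead or m < 4:
                # --- single-bead Gaussian displacement
                i = np.int64(rng.random() * m)
                nx = coords[i, 0] + bead_step * rng.standard_normal()
                ny = coords[i, 1] + bead_step * rng.standard_normal()
                nz = coords[i, 2] + bead_step * rng.standard_normal()
                if not _in_box(nx, ny, nz, box):
                    continue
                de = 0.0
                if i > 0:
                    dxo = coords[i, 0] - coords[i - 1, 0]
                    dyo = coords[i, 1] - coords[i - 1, 1]
                    dzo = coords[i, 2] - coords[i - 1, 2]
                    dxn = nx - coords[i - 1, 0]
                    dyn = ny - coords[i - 1, 1]
                    dzn = nz - coords[i - 1, 2]
                    de += 1.5 / (b * b) * (
                        dxn * dxn + dyn * dyn + dzn * dzn - dxo * dxo - dyo * dyo - dzo * dzo
                    )
                if i < m - 1:
                    dxo = coords[i + 1, 0] - coords[i, 0]
                    dyo = coords[i + 1, 1] - coords[i, 1]
                    dzo = coords[i + 1, 2] - coords[i, 2]
                    dxn = coords[i + 1, 0] - nx
                    dyn = coords[i + 1, 1] - ny
                    dzn = coords[i + 1, 2] - nz
                    de += 1.5 / (b * b) * (
                        dxn * dxn + dyn * dyn + dzn * dzn - dxo * dxo - dyo * dyo - dzo * dzo
                    )
                ncx, ncy, ncz = _cell_of(nx, ny, nz, cell, off)
                de_nb = 0.0
                if ncx != cells[i, 0] or ncy != cells[i, 1] or ncz != cells[i, 2]:
                    for j in range(m):
                        if j == i:
                            continue
                        if _same_cell(cells, i, j):
                            de_nb -= U[i, j]
                        if cells[j, 0] == ncx and cells[j, 1] == ncy and cells[j, 2] == ncz:
                            de_nb += U[i, j]
                de += de_nb
                if de <= 0.0 or rng.random() < np.exp(-de):
                    coords[i, 0] = nx
                    coords[i, 1] = ny
                    coords[i, 2] = nz
                    cells[i, 0] = ncx
                    cells[i, 1] = ncy
                    cells[i, 2] = ncz
                    e_nb += de_nb
                    n_acc += 1
            elif u < p_bead + p_crank:
                # --- crankshaft rotation of an interior segment
                i = np.int64(rng.random() * (m - 2))
                max_j = min(m - 1, i + 2 + crank_max_seg)
                j = i + 2 + np.int64(rng.random() * (max_j - i - 1))
                if j > m - 1:
                    j = m - 1
                ax = coords[j, 0] - coords[i, 0]
                ay = coords[j, 1] - coords[i, 1]
                az = coords[j, 2] - coords[i, 2]
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                if norm < 1e-12:
                    continue
                axis = np.empty(3)
                axis[0] = ax / norm
                axis[1] = ay / norm
                axis[2] = az / norm
                theta = (rng.random() * 2.0 - 1.0) * np.pi
                cos_t = np.cos(theta)
                sin_t = np.sin(theta)
                ok = True
                for a in range(i + 1, j):
                    px, py, pz = _rotate_about_axis(coords[a], coords[i], axis, cos_t, sin_t)
                    if not _in_box(px, py, pz, box):
                        ok = False
                        break
                    new_seg[a, 0] = px
                    new_seg[a, 1] = py
                    new_seg[a, 2] = pz
                if not ok:
                    continue
                # bonded energy is invariant: rotation about the line
                # through both anchor beads preserves all bond lengths
                e_old = _segment_energy(cells, U, i + 1, j)
                old_block = coords[i + 1 : j].copy()
                old_cells = cells[i + 1 : j].copy()
                for a in range(i + 1, j):
                    coords[a, 0] = new_seg[a, 0]
                    coords[a, 1] = new_seg[a, 1]
                    coords[a, 2] = new_seg[a, 2]
                    cx, cy, cz = _cell_of(coords[a, 0], coords[a, 1], coords[a, 2], cell, off)
                    cells[a, 0] = cx
                    cells[a, 1] = cy
                    cells[a, 2] = cz
                e_new = _segment_energy(cells, U, i + 1, j)
                de = e_new - e_old
                if de <= 0.0 or rng.random() < np.exp(-de):
                    e_nb += de
                    n_acc += 1
                else:
                    coords[i + 1 : j] = old_block
                    cells[i + 1 : j] = old_cells
            else:
                # --- whole-chain translation
                tx = trans_step * rng.standard_normal()
                ty = trans_step * rng.standard_normal()
                tz = trans_step * rng.standard_normal()
                ok = True
                for a in range(m):
                    if not _in_box(coords[a, 0] + tx, coords[a, 1] + ty, coords[a, 2] + tz, box):
                        ok = False
                        break
                if not ok:
                    continue
                old_coords = coords.copy()
                old_cells = cells.copy()
                for a in range(m):
                    coords[a, 0] += tx
                    coords[a, 1] += ty
                    coords[a, 2] += tz
                _assign_cells(coords, cell, off, cells)
                e_new = nonbonded_energy_nb(cells, U)
                de = e_new - e_nb
                if de <= 0.0 or rng.random() < np.exp(-de):
                    e_nb = e_new
                    n_acc += 1
                else:
                    coords[:] = old_coords
                    cells[:] = old_cells

            if debug_every > 0 and n_moves % debug_every == 0:
                drift = abs(e_nb - nonbonded_energy_nb(cells, U))
                if drift > max_drift:
                    max_drift = drift

        if sweep >= equil_sweeps:
            k = sweep - equil_sweeps
            if k % sweeps_between == 0:
                idx = k // sweeps_between
                if idx < n_samples:
                    samples[idx] = coords
                    offsets[idx, 0] = off[0]
                    offsets[idx, 1] = off[1]
                    offsets[idx, 2] = off[2]
                    n_recorded += 1

    return samples, offsets, n_acc, n_moves, max_drift


@njit(cache=True)
def contact_counts(samples, offsets, cell):
    """Count, per pair, the number of structures in which the beads co-cell."""
    n, m, _ = samples.shape
    counts = np.zeros((m, m), dtype=np.int64)
    cells = np.empty((m, 3), dtype=np.int64)
    for s in range(n):
        _assign_cells(samples[s], cell, offsets[s], cells)
        for i in range(m):
            for j in range(i + 1, m):
                if _same_cell(cells, i, j):
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts
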