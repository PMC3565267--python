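"""Numba-compiled hot loops: overlap checks, monomer-mode MC, pair histograms.

All kernels take a cubic box edge ``L`` and positions in ``[0, L)``; distances
use the minimum-image convention.  These are internal helpers — the public
surfaces live in ``mc`` and ``analysis``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _mi_dist2(dx: float, dy: float, dz: float, L: float) -> float:
    dx -= L * np.rint(dx / L)
    dy -= L * np.rint(dy / L)
    dz -= L * np.rint(dz / L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def any_overlap(positions: np.ndarray, p: np.ndarray, L: float, sigma2: float,
                skip: np.ndarray) -> bool:
    """True if point ``p`` is closer than sqrt(sigma2) to any position whose
    index is not flagged in the boolean ``skip`` mask."""
    n = positions.shape[0]
    for i in range(n):
        if skip[i]:
            continue
        if _mi_dist2(p[0] - positions[i, 0], p[1] - positions[i, 1],
                     p[2] - positions[i, 2], L) < sigma2:
            return True
    return False


@njit(cache=True)
def trials_free(positions: np.ndarray, trials: np.ndarray, L: float,
                sigma2: float, skip: np.ndarray) -> np.ndarray:
    """Overlap-free flag per trial position against all non-skipped sites."""
    m = trials.shape[0]
    out = np.ones(m, dtype=np.bool_)
    for t in range(m):
        out[t] = not any_overlap(positions, trials[t], L, sigma2, skip)
    return out


@njit(cache=True)
def _min_pair_brute(positions: np.ndarray, L: float) -> float:
    n = positions.shape[0]
    best = 1e300
    for i in range(n - 1):
        for j in range(i + 1, n):
            d2 = _mi_dist2(positions[i, 0] - positions[j, 0],
                           positions[i, 1] - positions[j, 1],
                           positions[i, 2] - positions[j, 2], L)
            if d2 < best:
                best = d2
    return np.sqrt(best)


def min_pair_distance(positions: np.ndarray, L: float) -> float:
    """Smallest minimum-image pair distance.

    Cell-list search where valid (a closest pair nearer than one cell edge
    is always found); falls back to brute force when the cell answer cannot
    be trusted (sparse systems whose closest pair exceeds the cell size).
    """
    ncell = int(L)
    if ncell >= 3 and positions.shape[0] > 32:
        head = np.empty(ncell**3, dtype=np.int64)
        nxt = np.empty(positions.shape[0], dtype=np.int64)
        cell_of = np.empty(positions.shape[0], dtype=np.int64)
        _build_cells(positions, L, ncell, head, nxt, cell_of)
        best = _min_pair_cells(positions, L, ncell, head, nxt)
        if best < L / ncell:
            return float(best)
    return float(_min_pair_brute(positions, L))


@njit(cache=True)
def _mc_brute(positions: np.ndarray, L: float, n_moves: int, max_disp: float) -> int:
    n = positions.shape[0]
    acc = 0
    for _ in range(n_moves):
        i = np.random.randint(n)
        px = positions[i, 0] + (np.random.random() - 0.5) * 2.0 * max_disp
        py = positions[i, 1] + (np.random.random() - 0.5) * 2.0 * max_disp
        pz = positions[i, 2] + (np.random.random() - 0.5) * 2.0 * max_disp
        px -= L * np.floor(px / L)
        py -= L * np.floor(py / L)
        pz -= L * np.floor(pz / L)
        ok = True
        for j in range(n):
            if j == i:
                continue
            if _mi_dist2(px - positions[j, 0], py - positions[j, 1],
                         pz - positions[j, 2], L) < 1.0:
                ok = False
                break
        if ok:
            positions[i, 0] = px
            positions[i, 1] = py
            positions[i, 2] = pz
            acc += 1
    return acc


@njit(cache=True)
def _build_cells(positions, L, ncell, head, nxt, cell_of):
    head[:] = -1
    n = positions.shape[0]
    for i in range(n):
        ix = int(positions[i, 0] / L * ncell) % ncell
        iy = int(positions[i, 1] / L * ncell) % ncell
        iz = int(positions[i, 2] / L * ncell) % ncell
        c = (ix * ncell + iy) * ncell + iz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i


@njit(cache=True)
def _cell_overlap(positions, L, ncell, head, nxt, px, py, pz, skip_i):
    ix = int(px / L * ncell) % ncell
    iy = int(py / L * ncell) % ncell
    iz = int(pz / L * ncell) % ncell
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                c = (((ix + dx) % ncell) * ncell + ((iy + dy) % ncell)) * ncell + (
                    (iz + dz) % ncell
                )
                j = head[c]
                while j >= 0:
                    if j != skip_i:
                        if _mi_dist2(px - positions[j, 0], py - positions[j, 1],
                                     pz - positions[j, 2], L) < 1.0:
                            return True
                    j = nxt[j]
    return False


@njit(cache=True)
def _mc_cells(positions, L, n_moves, max_disp, ncell, head, nxt, cell_of) -> int:
    n = positions.shape[0]
    acc = 0
    for _ in range(n_moves):
        i = np.random.randint(n)
        px = positions[i, 0] + (np.random.random() - 0.5) * 2.0 * max_disp
        py = positions[i, 1] + (np.random.random() - 0.5) * 2.0 * max_disp
        pz = positions[i, 2] + (np.random.random() - 0.5) * 2.0 * max_disp
        px -= L * np.floor(px / L)
        py -= L * np.floor(py / L)
        pz -= L * np.floor(pz / L)
        if _cell_overlap(positions, L, ncell, head, nxt, px, py, pz, i):
            continue
        positions[i, 0] = px
        positions[i, 1] = py
        positions[i, 2] = pz
        acc += 1
        ix = int(px / L * ncell) % ncell
        iy = int(py / L * ncell) % ncell
        iz = int(pz / L * ncell) % ncell
        c_new = (ix * ncell + iy) * ncell + iz
        c_old = cell_of[i]
        if c_new != c_old:
            # unlink i from its old cell
            j = head[c_old]
            if j == i:
                head[c_old] = nxt[i]
            else:
                while nxt[j] != i:
                    j = nxt[j]
                nxt[j] = nxt[i]
            nxt[i] = head[c_new]
            head[c_new] = i
            cell_of[i] = c_new
    return acc


def monomer_mc(positions: np.ndarray, L: float, n_moves: int, max_disp: float,
               seed: int) -> int:
    """Single-sphere displacement Metropolis MC for the monomer mode.

    Proposes uniform displacements in a cube of half-width ``max_disp``; a
    move is accepted iff it creates no hard-core overlap.  Positions are
    updated in place; returns the number of accepted moves.  Uses a linked
    cell list when the box is large enough, brute force otherwise.
    """
    np.random.seed(seed)
    ncell = int(L)
    if ncell < 3:
        return _mc_brute(positions, L, n_moves, max_disp)
    head = np.empty(ncell**3, dtype=np.int64)
    nxt = np.empty(positions.shape[0], dtype=np.int64)
    cell_of = np.empty(positions.shape[0], dtype=np.int64)
    _build_cells(positions, L, ncell, head, nxt, cell_of)
    return _mc_cells(positions, L, n_moves, max_disp, ncell, head, nxt, cell_of)


@njit(cache=True)
def _min_pair_cells(positions, L, ncell, head, nxt) -> float:
    best = 1e300
    n = positions.shape[0]
    for i in range(n):
        ix = int(positions[i, 0] / L * ncell) % ncell
        iy = int(positions[i, 1] / L * ncell) % ncell
        iz = int(positions[i, 2] / L * ncell) % ncell
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    c = (((ix + dx) % ncell) * ncell + ((iy + dy) % ncell)) * ncell + (
                        (iz + dz) % ncell
                    )
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            d2 = _mi_dist2(
                                positions[i, 0] - positions[j, 0],
                                positions[i, 1] - positions[j, 1],
                                positions[i, 2] - positions[j, 2], L)
                            if d2 < best:
                                best = d2
                        j = nxt[j]
    return np.sqrt(best)


@njit(cache=True)
def pair_histogram(positions: np.ndarray, L: float, r_max: float,
                   n_bins: int) -> np.ndarray:
    """Pair-distance histogram over minimum-image distances up to r_max."""
    n = positions.shape[0]
    hist = np.zeros(n_bins, dtype=np.int64)
    dr = r_max / n_bins
    r2max = r_max * r_max
    for i in range(n - 1):
        for j in range(i + 1, n):
            d2 = _mi_dist2(positions[i, 0] - positions[j, 0],
                           positions[i, 1] - positions[j, 1],
                           positions[i, 2] - positions[j, 2], L)
            if d2 < r2max:
                k = int(np.sqrt(d2) / dr)
                if k < n_bins:
                    hist[k] += 1
    return hist
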