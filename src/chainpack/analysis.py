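"""Scalar structure observables along trajectories.

Combines the pair radial distribution function g(r), the flipper mobility
statistic, CCE crystallinity and Voronoi shape means into per-frame records,
and locates the disorder-order transition as the window of steepest
crystallinity increase.

The flipper statistic is the translational-entropy proxy for chain packings:
an interior sphere is a *flipper* at amplitude dphi when it can rotate by
+dphi and by -dphi about the axis through its two bonded neighbours (a move
that preserves both bond lengths exactly) without creating any hard-core
overlap.  The feasibility test is purely geometric — no move is applied.
The fraction of flippers rises sharply when the local environments become
more symmetric during crystallization, signalling the gain in translational
entropy that drives the transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .core import SIGMA, ChainSystem, minimum_image_displacement, packing_fraction
from .voronoi import shape_measures, tessellate


@dataclass(frozen=True)
class GofRSpec:
    """Binning of the pair radial distribution function."""

    bin_width: float = 0.02
    r_max: float | None = None  # default L/2

    def edges(self, L_min: float) -> np.ndarray:
        r_max = self.r_max if self.r_max is not None else L_min / 2.0
        if r_max > L_min / 2.0 + 1e-12:
            raise ValueError(
                f"r_max={r_max} exceeds L/2={L_min / 2}; the minimum-image "
                "convention is only valid up to half the box edge"
            )
        n = int(math.floor(r_max / self.bin_width))
        return np.arange(n + 1) * self.bin_width


@dataclass(frozen=True)
class FlipperSpec:
    """Flip amplitudes (degrees); both senses are always required."""

    amplitudes: tuple[float, ...] = (0.01, 0.10, 1.00)
    #: also probe end spheres by rotation about a random perpendicular axis
    include_ends: bool = False

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("flip amplitudes must be positive")


def g_r(system: ChainSystem, spec: GofRSpec = GofRSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Ideal-gas-normalized pair correlation over minimum-image distances.

    Returns (bin centers, g).  All pairs (bonded and non-bonded) enter, as
    in the standard total g(r); values below contact vanish up to bin
    resolution.
    """
    L_min = float(np.min(system.box.edge_lengths))
    edges = spec.edges(L_min)
    n = system.n_at
    if system.box.is_cubic:
        hist = _kernels.pair_histogram(
            system.positions, system.box.edge_length, float(edges[-1]), edges.size - 1
        ).astype(float)
    else:
        hist = np.zeros(edges.size - 1)
        pos = system.positions
        for i in range(n - 1):
            d = minimum_image_displacement(pos[i], pos[i + 1 :], system.box)
            r = np.sqrt(np.sum(d * d, axis=1))
            hist += np.histogram(r, bins=edges)[0]
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = (n * (n - 1) / 2.0) * shell / system.box.volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / ideal


def contact_value(
    centers: np.ndarray,
    g: np.ndarray,
    counts: np.ndarray | None = None,
    window: float = 0.06,
    degree: int = 2,
) -> float:
    """Extrapolate g(r) to the contact value g(sigma+).

    Fits a low-order polynomial to the bins just above contact (optionally
    weighted by their pair counts) and evaluates it at r = sigma.
    """
    mask = (centers > SIGMA) & (centers < SIGMA + window)
    if mask.sum() < degree + 1:
        raise ValueError("not enough bins above contact for the fit")
    w = None if counts is None else np.sqrt(np.maximum(counts[mask], 1.0))
    coef = np.polyfit(centers[mask], g[mask], degree, w=w)
    return float(np.polyval(coef, SIGMA))


def compressibility_factor(phi: float, g_contact: float) -> float:
    """Hard-sphere virial equation of state: Z = 1 + 4 phi g(sigma+)."""
    return 1.0 + 4.0 * phi * g_contact


class FlipperFractions(dict):
    """Amplitude → flipper fraction mapping with an auditable denominator.

    ``n_eligible`` is the number of probed spheres (interior chain spheres
    only, unless end probing was requested), so the counting convention
    behind every fraction is explicit.
    """

    def __init__(self, fractions: dict[float, float], n_eligible: int):
        super().__init__(fractions)
        self.n_eligible = n_eligible


def flipper_fraction(
    system: ChainSystem, spec: FlipperSpec = FlipperSpec(), rng: np.random.Generator | None = None
) -> "FlipperFractions":
    """Fraction of eligible spheres that can flip both ways at each amplitude.

    Eligible spheres are interior chain spheres (two bonded neighbours);
    end spheres and monomers are excluded from the denominator unless
    ``include_ends`` probes ends about a random perpendicular axis.  The
    returned mapping carries ``n_eligible`` so the denominator convention
    is auditable.  The fraction is non-increasing in the amplitude (nested
    feasibility).  Raises for monomer-mode systems, which have no bonds to
    define a flip.
    """
    interior: list[tuple[int, int, int]] = []
    ends: list[tuple[int, int]] = []
    for c in system.chains:
        for k in range(1, c.size - 1):
            interior.append((int(c[k]), int(c[k - 1]), int(c[k + 1])))
        if c.size >= 2:
            ends.append((int(c[0]), int(c[1])))
            ends.append((int(c[-1]), int(c[-2])))
    if not interior and not (spec.include_ends and ends):
        raise ValueError(
            "no interior chain spheres: monomer-mode systems need a "
            "displacement-based mobility probe, not the flipper statistic"
        )
    pos = system.positions
    L = system.box.edge_lengths
    tree = cKDTree(pos, boxsize=L)
    if rng is None:
        rng = np.random.default_rng(0)

    # candidate blockers within reach of any rotated position
    out: dict[float, float] = {}
    cand_cache: dict[int, np.ndarray] = {}

    def blockers(site: int) -> np.ndarray:
        if site not in cand_cache:
            idx = tree.query_ball_point(pos[site], r=2.0 * SIGMA + 1e-9)
            cand_cache[site] = np.array([i for i in idx if i != site])
        return cand_cache[site]

    probes: list[tuple[int, np.ndarray, np.ndarray, set[int]]] = []
    for site, a, b in interior:
        axis_a, axis_b = pos[a], pos[b]
        probes.append((site, axis_a, axis_b, {site, a, b}))
    if spec.include_ends:
        for site, a in ends:
            d = minimum_image_displacement(pos[a], pos[site], system.box)
            perp = np.cross(d, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            probes.append((site, pos[a], pos[a] + perp, {site, a}))

    for amp in spec.amplitudes:
        ang = math.radians(amp)
        n_flip = 0
        for site, axis_a, axis_b, skip in probes:
            ok = True
            for sgn in (ang, -ang):
                p = _rotate(pos[site], axis_a, axis_b, sgn, L)
                cand = blockers(site)
                if cand.size:
                    d = p - pos[cand]
                    d -= L * np.round(d / L)
                    dist2 = np.sum(d * d, axis=1)
                    bad = dist2 < SIGMA**2 - 1e-12
                    if np.any(bad):
                        hit = cand[bad]
                        if any(h not in skip for h in hit):
                            ok = False
                            break
            if ok:
                n_flip += 1
        out[amp] = n_flip / len(probes)
    return FlipperFractions(out, n_eligible=len(probes))


def _rotate(p, a, b, angle, L):
    d = b - a
    d = d - L * np.round(d / L)
    axis = d / np.linalg.norm(d)
    v = p - a
    v = v - L * np.round(v / L)
    c, s = math.cos(angle), math.sin(angle)
    return a + v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


@dataclass
class TransitionReport:
    """Windows of steepest change of the three transition diagnostics."""

    transition_step: int | None
    tau_c_window: tuple[int, int] | None
    b_window: tuple[int, int] | None
    flipper_window: tuple[int, int] | None

    def colocated(self) -> bool | None:
        """Do the steepest tau_c-rise, b-fall and flipper-rise windows overlap?"""
        wins = [self.tau_c_window, self.b_window, self.flipper_window]
        wins = [w for w in wins if w is not None]
        if len(wins) < 2:
            return None
        lo = max(w[0] for w in wins)
        hi = min(w[1] for w in wins)
        return lo <= hi


def _steepest_window(
    steps: np.ndarray, values: np.ndarray, window: int, sign: float
) -> tuple[int, int] | None:
    if values.size < 2:
        return None
    w = min(window, values.size - 1)
    deltas = sign * (values[w:] - values[:-w])
    if np.all(deltas <= 1e-12):
        return None
    k = int(np.argmax(deltas))
    return int(steps[k]), int(steps[k + w])


def trajectory_report(
    frames: list[ChainSystem],
    steps: list[int] | None = None,
    gofr: GofRSpec | None = None,
    flippers: FlipperSpec | None = FlipperSpec(),
    cce_structures: tuple[str, ...] = ("hcp", "fcc", "fivefold"),
    threshold: float | None = None,
    gr_frames: tuple[int, ...] = (),
):
    """Per-frame observables and transition detection for a trajectory.

    Returns ``(table, transition, gr_curves)``: a tidy DataFrame with one
    row per frame (tau_c, S_X, mean shape measures, flipper fractions, phi),
    a :class:`TransitionReport` locating the steepest-change windows, and
    g(r) curves for the requested frame indices.  Flipper columns are
    omitted for monomer-mode trajectories (no bonds to flip about).
    """
    import pandas as pd

    from .cce import EPS_THRES, classify_frame

    if len(frames) < 2:
        raise ValueError("trajectory_report needs at least 2 frames")
    if steps is None:
        steps = list(range(len(frames)))
    thr = EPS_THRES if threshold is None else threshold

    has_bonds = any(c.size >= 3 for c in frames[0].chains)
    rows = []
    gr_curves = {}
    for f, sys_ in enumerate(frames):
        _, order = classify_frame(sys_, threshold=thr, structures=cce_structures)
        cells = tessellate(sys_)
        ms = [shape_measures(c) for c in cells]
        row = {
            "frame": f,
            "step": steps[f],
            "phi": packing_fraction(sys_),
            "S_hcp": order.S_hcp,
            "S_fcc": order.S_fcc,
            "S_5f": order.S_5f,
            "tau_c": order.tau_c,
            "mean_b": float(np.mean([m.b for m in ms])),
            "mean_c": float(np.mean([m.c for m in ms])),
            "mean_k2": float(np.mean([m.k2 for m in ms])),
            # total spheres over total cell volume (space-filling identity)
            "mean_local_density": len(cells) / float(np.sum([m.volume for m in ms])),
        }
        if has_bonds and flippers is not None:
            for amp, frac in flipper_fraction(sys_, flippers).items():
                row[f"flipper_{amp:g}"] = frac
        if f in gr_frames:
            spec = gofr or GofRSpec()
            gr_curves[f] = g_r(sys_, spec)
        rows.append(row)
    table = pd.DataFrame(rows)

    window = max(3, round(0.05 * len(frames)))
    st = np.asarray(steps)
    tau_w = _steepest_window(st, table["tau_c"].to_numpy(), window, +1.0)
    b_w = _steepest_window(st, table["mean_b"].to_numpy(), window, -1.0)
    fl_w = None
    fl_cols = [c for c in table.columns if c.startswith("flipper_")]
    if fl_cols:
        fl_w = _steepest_window(st, table[fl_cols[-1]].to_numpy(), window, +1.0)
    transition = TransitionReport(
        transition_step=None if tau_w is None else tau_w[1],
        tau_c_window=tau_w,
        b_window=b_w,
        flipper_window=fl_w,
    )
    return table, transition, gr_curves
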