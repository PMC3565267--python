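"""Metropolis Monte Carlo for athermal packings of tangent hard-sphere chains.

The move mix follows the production scheme for these systems: local moves
(reptation, end-sphere rotation, configurational-bias regrowth, inter-chain
reptation, internal libration) executed in a configurational-bias pattern
with multiple trial positions whose number grows with packing fraction, plus
the rare chain-connectivity-altering moves sEB and sIEB (simplified end
bridging and its intramolecular analog) that delete and re-form bonds
between properly selected sphere pairs to equilibrate chain lengths at long
range.  Simulations run in the n_at n_ch V T mu ensemble: sphere and chain
counts and the volume are fixed while individual chain lengths fluctuate
under per-length chemical-potential weights.

Because the interactions are hard, acceptance is purely geometric: a
proposal is accepted iff it creates no overlap, weighted by the Rosenbluth
factor ratio where configurational bias is used and by exp(delta mu*) where
chain lengths change.  Monomer mode (all chains of length 1) uses a
numba-compiled single-sphere displacement kernel and samples the plain
hard-sphere fluid — the reference system for the equation-of-state check.

Compression mimics the generation protocol for dense states: frequent small
isotropic cell shrinkages with affine repositioning of chains — each chain
is moved rigidly so that its first sphere scales affinely with the box —
with MC relaxation between attempts, until the target packing fraction is
reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .core import (
    SIGMA,
    ChainSystem,
    ConfigurationError,
    EnsembleSpec,
    packing_fraction,
    validate,
)

_MOVES = (
    "reptation",
    "end_rotation",
    "config_bias",
    "interchain_reptation",
    "internal_libration",
    "seb",
    "sieb",
)


@dataclass(frozen=True)
class MoveMix:
    """Attempt probabilities of the seven-move mix.

    Defaults are the production mix for dense chain packings; the two
    connectivity-altering moves get 0.01% each so the seven probabilities
    sum to exactly one.
    """

    reptation: float = 0.10
    end_rotation: float = 0.10
    config_bias: float = 0.20
    interchain_reptation: float = 0.25
    internal_libration: float = 0.3498
    seb: float = 0.0001
    sieb: float = 0.0001

    def __post_init__(self) -> None:
        p = self.probabilities()
        if np.any(p < 0):
            raise ConfigurationError("move probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"move probabilities sum to {p.sum()}, not 1")

    def probabilities(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in _MOVES])

    @staticmethod
    def monomer() -> "MoveMix":
        """Degenerate mix for monomer mode (single-sphere displacements)."""
        return MoveMix(0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CBSchedule:
    """Number of trial positions per displaced site as a function of phi.

    ``breaks`` are packing-fraction thresholds; ``trials[i]`` applies below
    ``breaks[i]``, ``trials[-1]`` above the last break.  Non-decreasing.
    """

    breaks: tuple[float, ...] = (0.45, 0.58)
    trials: tuple[int, ...] = (10, 30, 50)

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.breaks) + 1:
            raise ConfigurationError("need len(trials) == len(breaks) + 1")
        if any(t < 1 for t in self.trials) or any(
            a > b for a, b in zip(self.trials, self.trials[1:])
        ):
            raise ConfigurationError("trial counts must be >= 1 and non-decreasing")

    def k(self, phi: float) -> int:
        for br, t in zip(self.breaks, self.trials):
            if phi < br:
                return t
        return self.trials[-1]


@dataclass(frozen=True)
class RunSpec:
    """Length, recording cadence and sampling parameters of one MC run."""

    n_steps: int
    seed: int = 0
    record_every: int = 200_000
    movemix: MoveMix = field(default_factory=MoveMix)
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    cb_schedule: CBSchedule = field(default_factory=CBSchedule)
    #: half-amplitude of the internal-libration rotation, radians
    libration_delta: float = math.radians(20.0)
    #: regrown segment length ceiling for configurational-bias regrowth
    cb_max_segment: int = 3
    #: search-shell width above tangency for sEB/sIEB acceptor candidates
    bridge_search: float = 1e-2

    def __post_init__(self) -> None:
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")


@dataclass
class MCResult:
    """Recorded frames, their step indices, and acceptance statistics."""

    frames: list[ChainSystem]
    steps: list[int]
    attempted: dict[str, int]
    accepted: dict[str, int]
    mu: dict[int, float]

    def acceptance_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "move": list(self.attempted),
                "attempted": list(self.attempted.values()),
                "accepted": [self.accepted[m] for m in self.attempted],
            }
        )


def _unit_sphere(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class _Engine:
    """Working state of one MC run; mutates a private copy of the system."""

    def __init__(self, system: ChainSystem, spec: RunSpec):
        if not system.box.is_cubic:
            raise ConfigurationError("MC requires a cubic box")
        self.sys = system.copy()
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.L = system.box.edge_length
        self.k_trials = spec.cb_schedule.k(packing_fraction(system))
        self.attempted = {m: 0 for m in _MOVES}
        self.accepted = {m: 0 for m in _MOVES}
        self.mu = dict(spec.ensemble.chemical_potentials or {})
        self._cumprobs = np.cumsum(spec.movemix.probabilities())
        self._skip = np.zeros(self.sys.n_at, dtype=np.bool_)

    # -- geometry helpers ---------------------------------------------------

    def _free(self, trials: np.ndarray, exclude: np.ndarray) -> np.ndarray:
        """Overlap-free flag per trial against all sites except ``exclude``.

        Uses the same EPS_NUM slack as validate(): tangency-shell trials sit
        at exactly sigma from their bonded anchor and must not be flagged by
        round-off.
        """
        from .core import EPS_NUM

        skip = self._skip
        skip[exclude] = True
        out = _kernels.trials_free(
            self.sys.positions, np.atleast_2d(trials), self.L,
            (SIGMA - EPS_NUM) ** 2, skip
        )
        skip[exclude] = False
        return out

    def _shell_trials(self, center: np.ndarray, k: int) -> np.ndarray:
        """k points on the tangency sphere of ``center``."""
        return self.sys.box.wrap(center + SIGMA * _unit_sphere(self.rng, k))

    def _circle_trials(
        self, a: np.ndarray, b: np.ndarray, k: int
    ) -> np.ndarray | None:
        """k points tangent to spheres at both a and b (their shell circle)."""
        d = self.sys.box.wrap(b - a + self.L / 2) - self.L / 2  # min image of b-a
        dist = float(np.linalg.norm(d))
        if dist >= 2.0 * SIGMA or dist < 1e-12:
            return None
        mid = a + 0.5 * d
        rho = math.sqrt(SIGMA**2 - 0.25 * dist**2)
        axis = d / dist
        e1 = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(axis, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        th = self.rng.uniform(0.0, 2.0 * math.pi, k)
        pts = mid + rho * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))
        return self.sys.box.wrap(pts)

    def _mu_of(self, n: int) -> float:
        return self.mu.get(n, 0.0)

    def _length_ok(self, n: int) -> bool:
        lo, hi = self.spec.ensemble.length_range()
        return lo <= n <= hi

    # -- moves --------------------------------------------------------------

    def step(self) -> None:
        move = _MOVES[int(np.searchsorted(self._cumprobs, self.rng.random()))]
        self.attempted[move] += 1
        ok = getattr(self, "_mv_" + move)()
        if ok:
            self.accepted[move] += 1

    def _pick_chain(self, min_len: int = 1) -> int | None:
        order = self.rng.permutation(self.sys.n_ch)
        for ci in order:
            if self.sys.chains[ci].size >= min_len:
                return int(ci)
        return None

    def _regrow_end(
        self, chain: np.ndarray, tail: bool, n_sites: int
    ) -> tuple[np.ndarray, float, float] | None:
        """Configurational-bias regrowth of ``n_sites`` spheres at one end.

        Returns (new positions, log W_new, log W_old) or None when the
        forward growth dies.  ``tail=True`` regrows the last sites.
        """
        k = self.k_trials
        seg = chain[-n_sites:] if tail else chain[:n_sites][::-1]
        kept = chain[:-n_sites] if tail else chain[n_sites:]
        anchor_idx = kept[-1] if tail else kept[0]
        pos = self.sys.positions
        logw_new = 0.0
        logw_old = 0.0
        new_pts = []
        anchor_new = pos[anchor_idx]
        anchor_old = pos[anchor_idx]
        for s, site in enumerate(seg):
            # forward: the whole old segment is stale (being replaced); the
            # grown predecessors are checked against explicitly
            trials = self._shell_trials(anchor_new, k)
            free = self._free(trials, seg)
            for p in new_pts[:-1]:
                d = self.sys.box.wrap(trials - p + self.L / 2) - self.L / 2
                free &= np.sum(d * d, axis=1) >= SIGMA**2
            n_new = int(free.sum())
            if n_new == 0:
                return None
            idx_free = np.nonzero(free)[0]
            choice = trials[idx_free[self.rng.integers(idx_free.size)]]
            new_pts.append(choice)
            logw_new += math.log(n_new)

            # reverse: the actual old position plus k-1 fresh trials, in the
            # old configuration (outer old sites not yet regrown are absent)
            trials_o = np.concatenate(
                [pos[site][None], self._shell_trials(anchor_old, k - 1)]
            ) if k > 1 else pos[site][None]
            free_o = self._free(trials_o, seg[s:])
            logw_old += math.log(max(int(free_o.sum()), 1))
            anchor_new = choice
            anchor_old = pos[site]
        return np.array(new_pts), logw_new, logw_old

    def _accept_rosenbluth(self, logw_new: float, logw_old: float,
                           extra_log: float = 0.0) -> bool:
        arg = logw_new - logw_old + extra_log
        return arg >= 0.0 or self.rng.random() < math.exp(arg)

    def _mv_reptation(self) -> bool:
        ci = self._pick_chain(min_len=2)
        if ci is None:
            return False
        chain = self.sys.chains[ci]
        k = self.k_trials
        pos = self.sys.positions
        head = bool(self.rng.integers(2))  # remove head sphere, regrow at tail
        removed = chain[0] if head else chain[-1]
        new_anchor = chain[-1] if head else chain[0]
        old_anchor = chain[1] if head else chain[-2]

        trials = self._shell_trials(pos[new_anchor], k)
        free = self._free(trials, np.array([removed]))
        n_new = int(free.sum())
        if n_new == 0:
            return False
        idx_free = np.nonzero(free)[0]
        choice = trials[idx_free[self.rng.integers(idx_free.size)]]
        trials_o = np.concatenate(
            [pos[removed][None], self._shell_trials(pos[old_anchor], k - 1)]
        ) if k > 1 else pos[removed][None]
        n_old = int(self._free(trials_o, np.array([removed])).sum())
        if not self._accept_rosenbluth(math.log(n_new), math.log(max(n_old, 1))):
            return False
        pos[removed] = choice
        self.sys.chains[ci] = (
            np.concatenate([chain[1:], [removed]])
            if head
            else np.concatenate([[removed], chain[:-1]])
        )
        return True

    def _mv_end_rotation(self) -> bool:
        ci = self._pick_chain(min_len=2)
        if ci is None:
            return False
        chain = self.sys.chains[ci]
        k = self.k_trials
        pos = self.sys.positions
        head = bool(self.rng.integers(2))
        site = chain[0] if head else chain[-1]
        anchor = chain[1] if head else chain[-2]
        trials = self._shell_trials(pos[anchor], k)
        free = self._free(trials, np.array([site]))
        n_new = int(free.sum())
        if n_new == 0:
            return False
        idx_free = np.nonzero(free)[0]
        choice = trials[idx_free[self.rng.integers(idx_free.size)]]
        trials_o = np.concatenate(
            [pos[site][None], self._shell_trials(pos[anchor], k - 1)]
        ) if k > 1 else pos[site][None]
        n_old = int(self._free(trials_o, np.array([site])).sum())
        if not self._accept_rosenbluth(math.log(n_new), math.log(max(n_old, 1))):
            return False
        pos[site] = choice
        return True

    def _mv_config_bias(self) -> bool:
        ci = self._pick_chain(min_len=2)
        if ci is None:
            return False
        chain = self.sys.chains[ci]
        max_seg = min(self.spec.cb_max_segment, chain.size - 1)
        n_sites = int(self.rng.integers(1, max_seg + 1))
        tail = bool(self.rng.integers(2))
        out = self._regrow_end(chain, tail, n_sites)
        if out is None:
            return False
        new_pts, lw_new, lw_old = out
        if not self._accept_rosenbluth(lw_new, lw_old):
            return False
        seg = chain[-n_sites:] if tail else chain[:n_sites][::-1]
        self.sys.positions[seg] = new_pts
        return True

    def _mv_interchain_reptation(self) -> bool:
        if self.sys.n_ch < 2:
            return False
        ca, cb = self.rng.choice(self.sys.n_ch, size=2, replace=False)
        A, B = self.sys.chains[ca], self.sys.chains[cb]
        if A.size < 2:
            return False
        if not (self._length_ok(A.size - 1) and self._length_ok(B.size + 1)):
            return False
        pos = self.sys.positions
        k = self.k_trials
        head_a = bool(self.rng.integers(2))
        moved = A[0] if head_a else A[-1]
        old_anchor = A[1] if head_a else A[-2]
        head_b = bool(self.rng.integers(2))
        new_anchor = B[0] if head_b else B[-1]

        trials = self._shell_trials(pos[new_anchor], k)
        free = self._free(trials, np.array([moved]))
        n_new = int(free.sum())
        if n_new == 0:
            return False
        idx_free = np.nonzero(free)[0]
        choice = trials[idx_free[self.rng.integers(idx_free.size)]]
        trials_o = np.concatenate(
            [pos[moved][None], self._shell_trials(pos[old_anchor], k - 1)]
        ) if k > 1 else pos[moved][None]
        n_old = int(self._free(trials_o, np.array([moved])).sum())
        dmu = (
            self._mu_of(A.size - 1)
            + self._mu_of(B.size + 1)
            - self._mu_of(A.size)
            - self._mu_of(B.size)
        )
        if not self._accept_rosenbluth(math.log(n_new), math.log(max(n_old, 1)), dmu):
            return False
        pos[moved] = choice
        self.sys.chains[ca] = A[1:] if head_a else A[:-1]
        self.sys.chains[cb] = (
            np.concatenate([[moved], B]) if head_b else np.concatenate([B, [moved]])
        )
        return True

    def _mv_internal_libration(self) -> bool:
        ci = self._pick_chain(min_len=3)
        if ci is None:
            return False
        chain = self.sys.chains[ci]
        j = int(self.rng.integers(1, chain.size - 1))
        site, a, b = chain[j], chain[j - 1], chain[j + 1]
        pos = self.sys.positions
        new_p = _rotate_about_axis(
            pos[site], pos[a], pos[b],
            self.rng.uniform(-self.spec.libration_delta, self.spec.libration_delta),
            self.L,
        )
        new_p = self.sys.box.wrap(new_p)
        if not self._free(new_p, np.array([site, a, b]))[0]:
            return False
        pos[site] = new_p
        return True

    # -- connectivity-altering moves -----------------------------------------

    def _bridge_candidates(self, end_pos: np.ndarray, forbidden: set[int]) -> np.ndarray:
        """Non-bonded spheres within the tangency search shell of an end."""
        pos = self.sys.positions
        d = self.sys.box.wrap(pos - end_pos + self.L / 2) - self.L / 2
        dist = np.linalg.norm(d, axis=1)
        hi = SIGMA + self.sys.tangency_tol + self.spec.bridge_search
        cand = np.nonzero((dist >= SIGMA) & (dist <= hi))[0]
        return np.array([c for c in cand if c not in forbidden], dtype=np.int64)

    def _mv_seb(self) -> bool:
        """End of chain A attacks a sphere of chain B; a tail transfers.

        The attacked sphere j is re-bonded to the attacking end and its bond
        toward the transferred side is deleted; j is regrown onto the exact
        tangency circle of the end and its kept neighbour so the tangency
        condition holds exactly in the new bonds.
        """
        ci = self._pick_chain(min_len=1)
        if ci is None:
            return False
        A = self.sys.chains[ci]
        head_a = bool(self.rng.integers(2))
        end = A[0] if head_a else A[-1]
        cid, idx = self.sys.chain_ids()
        forbidden = set(A.tolist())
        cands = self._bridge_candidates(self.sys.positions[end], forbidden)
        if cands.size == 0:
            return False
        j = int(self.rng.choice(cands))
        cj = int(cid[j])
        B = self.sys.chains[cj]
        t = int(idx[j])
        # transfer j..end-of-B (choose the side away from a random kept part)
        if bool(self.rng.integers(2)):
            tail_sites = B[t:]
            keep = B[:t]
            kept_neighbor = B[t + 1] if t + 1 < B.size else None
        else:
            tail_sites = B[: t + 1][::-1]
            keep = B[t + 1:]
            kept_neighbor = B[t - 1] if t - 1 >= 0 else None
        if keep.size == 0:
            return False  # whole-chain transfer would delete a chain
        if not (
            self._length_ok(keep.size) and self._length_ok(A.size + tail_sites.size)
        ):
            return False
        return self._do_bridge(ci, head_a, end, j, kept_neighbor, tail_sites,
                               cj, keep,
                               dmu=self._mu_of(keep.size)
                               + self._mu_of(A.size + tail_sites.size)
                               - self._mu_of(A.size) - self._mu_of(B.size))

    def _mv_sieb(self) -> bool:
        """Intramolecular end bridging: an end re-bonds to an interior sphere
        of its own chain and the complementary bond is deleted, reversing the
        intervening segment; the chain stays linear and its length fixed."""
        ci = self._pick_chain(min_len=5)
        if ci is None:
            return False
        C = self.sys.chains[ci]
        head = bool(self.rng.integers(2))
        end = C[0] if head else C[-1]
        forbidden = {int(C[0]), int(C[1]), int(C[-1]), int(C[-2])}
        cid, idx = self.sys.chain_ids()
        cands = self._bridge_candidates(self.sys.positions[end], set())
        cands = np.array(
            [c for c in cands if cid[c] == ci and c not in forbidden],
            dtype=np.int64,
        )
        if cands.size == 0:
            return False
        j = int(self.rng.choice(cands))
        t = int(idx[j])
        if head:
            # end C[0] bonds to j = C[t]; the bond (C[t-1], C[t]) is deleted
            # and the head segment reverses: C[t-1]..C[0], j, C[t+1]..
            kept_neighbor = C[t + 1] if t + 1 < C.size else None
            new_chain = np.concatenate([C[:t][::-1], [j], C[t + 1:]])
        else:
            # end C[-1] bonds to j; bond (C[t], C[t+1]) deleted, tail reverses
            kept_neighbor = C[t - 1] if t - 1 >= 0 else None
            new_chain = np.concatenate([C[:t], [j], C[t + 1:][::-1]])
        if kept_neighbor is None:
            return False
        return self._do_bridge(ci, head, end, j, kept_neighbor, None, ci,
                               new_chain, dmu=0.0)

    def _do_bridge(self, ci, head_a, end, j, kept_neighbor, tail_sites,
                   cj, keep_or_new, dmu) -> bool:
        """Shared acceptance step: regrow j on the exact tangency locus."""
        pos = self.sys.positions
        k = self.k_trials
        if kept_neighbor is None:
            trials = self._shell_trials(pos[end], k)
        else:
            trials = self._circle_trials(pos[end], pos[kept_neighbor], k)
            if trials is None:
                return False
        free = self._free(trials, np.array([j]))
        n_new = int(free.sum())
        if n_new == 0:
            return False
        idx_free = np.nonzero(free)[0]
        choice = trials[idx_free[self.rng.integers(idx_free.size)]]
        # reverse weight from the old bonded neighbours of j
        old_nb = self._old_neighbors_of(j)
        if len(old_nb) == 2:
            trials_o = self._circle_trials(pos[old_nb[0]], pos[old_nb[1]], k - 1)
        elif len(old_nb) == 1:
            trials_o = self._shell_trials(pos[old_nb[0]], k - 1)
        else:
            trials_o = None
        stack = [pos[j][None]] + ([trials_o] if trials_o is not None else [])
        n_old = int(self._free(np.concatenate(stack), np.array([j])).sum())
        if not self._accept_rosenbluth(math.log(n_new), math.log(max(n_old, 1)), dmu):
            return False
        pos[j] = choice
        if tail_sites is None:  # sIEB: rewire one chain
            self.sys.chains[ci] = keep_or_new
        else:  # sEB: tail moves from chain cj to chain ci
            A = self.sys.chains[ci]
            attached = np.concatenate([[j], tail_sites[1:]])
            self.sys.chains[ci] = (
                np.concatenate([attached[::-1], A])
                if head_a
                else np.concatenate([A, attached])
            )
            self.sys.chains[cj] = keep_or_new
        return True

    def _old_neighbors_of(self, j: int) -> list[int]:
        cid, idx = self.sys.chain_ids()
        C = self.sys.chains[int(cid[j])]
        t = int(idx[j])
        out = []
        if t > 0:
            out.append(int(C[t - 1]))
        if t + 1 < C.size:
            out.append(int(C[t + 1]))
        return out


def _rotate_about_axis(p, a, b, angle, L):
    """Rotate p about the axis through a and b (minimum-image) by angle."""
    d = b - a
    d = d - L * np.round(d / L)
    axis = d / np.linalg.norm(d)
    v = p - a
    v = v - L * np.round(v / L)
    c, s = math.cos(angle), math.sin(angle)
    v_rot = v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)
    return a + v_rot


def run_mc(system: ChainSystem, spec: RunSpec) -> MCResult:
    """Run the seven-move MC mix; returns recorded frames and statistics.

    The starting state must validate cleanly.  n_at, n_ch and the box are
    conserved; without connectivity-altering moves every chain length is
    conserved, with them lengths stay inside the ensemble's allowed range.
    """
    rep = validate(system)
    if not rep.ok:
        raise ConfigurationError(f"invalid start state: {rep}")

    if all(c.size == 1 for c in system.chains) and system.n_ch > 0:
        return _run_monomer(system, spec)

    eng = _Engine(system, spec)
    frames: list[ChainSystem] = []
    steps: list[int] = []
    for step in range(1, spec.n_steps + 1):
        eng.step()
        if step % spec.record_every == 0 or step == spec.n_steps:
            frames.append(eng.sys.copy())
            steps.append(step)
    if not frames:
        frames, steps = [eng.sys.copy()], [0]
    return MCResult(frames, steps, eng.attempted, eng.accepted, eng.mu)


def _run_monomer(system: ChainSystem, spec: RunSpec) -> MCResult:
    """Monomer mode: numba displacement kernel, same equilibrium ensemble."""
    if not system.box.is_cubic:
        raise ConfigurationError("MC requires a cubic box")
    sysm = system.copy()
    L = sysm.box.edge_length
    rng = np.random.default_rng(spec.seed)
    phi = packing_fraction(sysm)
    # displacement tuned to the free-path scale; acceptance lands mid-range
    max_disp = max(0.05, 0.5 * (phi ** (-1.0 / 3.0) - 1.0))
    frames, steps = [], []
    attempted = accepted = 0
    done = 0
    while done < spec.n_steps:
        block = min(spec.record_every, spec.n_steps - done)
        acc = _kernels.monomer_mc(
            sysm.positions, L, block, max_disp, int(rng.integers(2**31 - 1))
        )
        attempted += block
        accepted += acc
        done += block
        frames.append(sysm.copy())
        steps.append(done)
    if not frames:
        frames, steps = [sysm.copy()], [0]
    att = {m: 0 for m in _MOVES}
    acc_d = {m: 0 for m in _MOVES}
    att["config_bias"], acc_d["config_bias"] = attempted, accepted
    return MCResult(frames, steps, att, acc_d, {})


# ---------------------------------------------------------------------------
# compression and generation checks


class CompressionError(RuntimeError):
    """Target packing fraction not reached; carries the last valid state."""

    def __init__(self, msg: str, system: ChainSystem, phi: float):
        super().__init__(msg)
        self.system = system
        self.phi = phi


def compress(
    system: ChainSystem,
    phi_target: float,
    spec: RunSpec,
    shrink_factor: float = 0.999,
    attempt_every: int = 2000,
    max_attempts: int = 20_000,
) -> ChainSystem:
    """Compress by repeated isotropic shrinkage with affine chain repositioning.

    Each attempt rescales the box edge by a factor s < 1 and repositions
    every chain rigidly: its first sphere moves affinely (r -> s r) and the
    whole chain translates with it, leaving intra-chain geometry untouched.
    An attempt that would create any overlap is rejected and retried with a
    smaller step after further MC relaxation.  Returns a state with phi in
    [phi_target, phi_target + 1e-4].
    """
    if not system.box.is_cubic:
        raise ConfigurationError("compression requires a cubic box")
    phi0 = packing_fraction(system)
    if phi_target <= phi0:
        raise ConfigurationError(f"phi_target {phi_target} <= current {phi0}")

    from .core import SimulationBox  # local import to avoid cycle noise

    cur = system.copy()
    monomeric = all(c.size == 1 for c in cur.chains)
    rng = np.random.default_rng(spec.seed + 7)

    if monomeric:
        # fast path: single-sphere relaxation kernel, deterministic safe
        # shrink (all pair distances scale with the box, so any factor
        # s >= sigma/min_dist keeps the packing overlap-free)
        pos = cur.positions.copy()
        L = cur.box.edge_length
        n = pos.shape[0]
        stall = 0
        # aim a hair beyond the target so the shrink-factor product cannot
        # asymptote just below it in floating point; still lands well
        # inside [phi_target, phi_target + 1e-4]
        phi_aim = phi_target * (1.0 + 1e-9)
        for _ in range(max_attempts):
            phi = n * (math.pi / 6.0) * SIGMA**3 / L**3
            if phi >= phi_target:
                box = SimulationBox(L)
                return ChainSystem(pos, cur.chains, box, cur.tangency_tol)
            s_target = (phi / phi_aim) ** (1.0 / 3.0)
            dmin = _kernels.min_pair_distance(pos, L)
            # shrink to 90% of the available gap: leaving the closest pair a
            # little room keeps it mobile for the next relaxation burst
            s = max(s_target, 1.0 - 0.9 * (dmin - SIGMA), shrink_factor)
            if s < 1.0 - 1e-15:
                pos *= s
                L *= s
                stall = 0
            else:
                stall += 1
            # flat relaxation effort per attempt keeps the quench rapid in
            # MC time (a dense monomer packing starts ordering if it is
            # given long relaxation at high density); the effort quadruples
            # only when progress stalls on a caged closest pair
            m = attempt_every
            if stall > 2:
                m *= 4
            disp = min(0.12, max(0.02, 2.0 * (dmin - SIGMA)))
            _kernels.monomer_mc(pos, L, m, disp, int(rng.integers(2**31 - 1)))
        phi = n * (math.pi / 6.0) * SIGMA**3 / L**3
        raise CompressionError(
            f"failed to reach phi={phi_target} within {max_attempts} attempts "
            f"(reached {phi:.4f})",
            ChainSystem(pos, cur.chains, SimulationBox(L), cur.tangency_tol),
            phi,
        )

    relax = replace(spec, n_steps=attempt_every, record_every=max(attempt_every, 1))
    step = 1.0 - shrink_factor
    for _ in range(max_attempts):
        phi = packing_fraction(cur)
        if phi >= phi_target:
            return cur
        s_target = (phi / phi_target) ** (1.0 / 3.0)
        s = max(s_target, 1.0 - step)
        trial = _affine_chain_rescale(cur, s)
        if trial is not None:
            cur = trial
            step = min(step * 1.25, 1.0 - shrink_factor)
        else:
            step = max(step * 0.5, 1e-6)
        relax = replace(relax, seed=int(rng.integers(2**31 - 1)))
        cur = run_mc(cur, relax).frames[-1]

    raise CompressionError(
        f"failed to reach phi={phi_target} within {max_attempts} attempts "
        f"(reached {packing_fraction(cur):.4f})",
        cur,
        packing_fraction(cur),
    )


def _affine_chain_rescale(system: ChainSystem, s: float) -> ChainSystem | None:
    """Shrink the box by s, repositioning each chain rigidly via its first
    sphere; None if the result has any overlap."""
    from .core import SimulationBox

    L_new = system.box.edge_length * s
    new_pos = np.empty_like(system.positions)
    for c in system.chains:
        first = system.positions[c[0]]
        shift = first * s - first
        # translate the whole chain with its (affinely moved) first sphere
        coords = _unwrap(system, c)
        new_pos[c] = coords + shift
    trial = ChainSystem(new_pos, system.chains, SimulationBox(L_new),
                        system.tangency_tol)
    rep = validate(trial)
    return trial if rep.ok else None


def _unwrap(system: ChainSystem, chain: np.ndarray) -> np.ndarray:
    out = np.empty((chain.size, 3))
    out[0] = system.positions[chain[0]]
    L = system.box.edge_lengths
    for k in range(1, chain.size):
        d = system.positions[chain[k]] - system.positions[chain[k - 1]]
        d -= L * np.round(d / L)
        out[k] = out[k - 1] + d
    return out


def split_chains(system: ChainSystem) -> ChainSystem:
    """Halve every chain by deleting its central bond; positions untouched.

    A generation-protocol check: structural measures of a packing must not
    depend on whether it was grown at length N or produced by splitting a
    2N configuration.
    """
    for i, c in enumerate(system.chains):
        if c.size % 2:
            raise ConfigurationError(f"chain {i} has odd length {c.size}")
    new_chains: list[np.ndarray] = []
    for c in system.chains:
        h = c.size // 2
        new_chains.append(c[:h].copy())
        new_chains.append(c[h:].copy())
    return ChainSystem(
        system.positions.copy(), new_chains, system.box, system.tangency_tol
    )


def monomer_fluid(
    n: int,
    phi: float,
    seed: int,
    equilibrate: int = 0,
    start_phi: float = 0.10,
    attempt_every: int = 800,
) -> ChainSystem:
    """Equilibrium-ready hard-sphere monomer fluid at packing fraction phi.

    Inserts spheres by random sequential addition at ``min(phi, start_phi)``,
    compresses to the target, and optionally runs ``equilibrate`` single-
    sphere MC moves.  Deterministic for a given seed.
    """
    from .core import SimulationBox, box_for_phi

    rng = np.random.default_rng(seed)
    phi0 = min(phi, start_phi)
    box = box_for_phi(n, phi0)
    L = box.edge_length
    pos = np.empty((n, 3))
    placed = 0
    trials = 0
    while placed < n:
        p = rng.random(3) * L
        d = pos[:placed] - p
        d -= L * np.round(d / L)
        if placed == 0 or np.all(np.sum(d * d, axis=1) >= SIGMA**2):
            pos[placed] = p
            placed += 1
        trials += 1
        if trials > 5000 * n:
            raise ConfigurationError(f"insertion stalled at phi={phi0}")
    chains = [np.array([i]) for i in range(n)]
    system = ChainSystem(pos, chains, SimulationBox(L))
    if phi > phi0 + 1e-12:
        spec = RunSpec(n_steps=0, seed=int(rng.integers(2**31 - 1)))
        system = compress(system, phi, spec, attempt_every=attempt_every,
                          max_attempts=120_000)
    if equilibrate > 0:
        _kernels.monomer_mc(
            system.positions,
            system.box.edge_length,
            equilibrate,
            0.12,
            int(rng.integers(2**31 - 1)),
        )
    return system


# ---------------------------------------------------------------------------
# chemical-potential calibration (Wang-Landau style)


def calibrate_mu(
    system: ChainSystem,
    spec: RunSpec,
    rounds: int = 6,
    moves_per_round: int = 30_000,
) -> dict[int, float]:
    """Solve the chemical-potential profile shaping the length distribution.

    Stochastic feedback with iterate averaging: each round runs an MC burst
    under the current mu* profile, measures the empirical length histogram,
    and nudges ``mu* += eta (log target - log empirical)``.  Because n_at
    and n_ch are both conserved, mu* profiles that differ by an affine
    function of N are physically equivalent (the term b*sum(N_i) is a
    constant of motion), so each update is projected onto the quotient
    space by removing its least-squares affine part — without this the
    uncontrollable affine component of the feedback signal accumulates as
    unbounded drift.  Every achievable marginal automatically has mean
    n_at/n_ch, which both target distributions share, so the projected
    feedback converges; sampling noise is suppressed by averaging the mu*
    iterates over the second half of the rounds.
    """
    lengths, target = spec.ensemble.target_pmf()
    nlen = lengths.size
    mu_arr = np.zeros(nlen)
    base = spec.ensemble.chemical_potentials or {}
    for k, n in enumerate(lengths):
        mu_arr[k] = base.get(int(n), 0.0)
    cur = system.copy()
    rng = np.random.default_rng(spec.seed + 13)
    eta = 0.5
    # orthonormal basis of the affine (gauge) subspace in profile space
    ones = np.ones(nlen) / math.sqrt(nlen)
    lin = lengths - lengths.mean()
    lin = lin / np.linalg.norm(lin)

    def project(v: np.ndarray) -> np.ndarray:
        return v - (v @ ones) * ones - (v @ lin) * lin

    tail: list[np.ndarray] = []
    for r in range(rounds):
        ens = replace(
            spec.ensemble,
            chemical_potentials={int(n): float(m) for n, m in zip(lengths, mu_arr)},
        )
        sub = replace(
            spec,
            ensemble=ens,
            n_steps=moves_per_round,
            record_every=min(max(moves_per_round // 30, 1), 5000),
            seed=int(rng.integers(2**31 - 1)),
        )
        res = run_mc(cur, sub)
        cur = res.frames[-1]
        counts = np.zeros(nlen)
        for fr in res.frames:
            for l in fr.chain_lengths():
                k = np.searchsorted(lengths, l)
                if k < nlen and lengths[k] == l:
                    counts[k] += 1
        emp = (counts + 0.5) / (counts.sum() + 0.5 * nlen)
        mu_arr = project(mu_arr + eta * (np.log(target) - np.log(emp)))
        if r >= rounds // 2:
            tail.append(mu_arr.copy())
    mu_arr = np.mean(tail, axis=0) if tail else mu_arr
    return {int(n): float(m) for n, m in zip(lengths, mu_arr)}
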