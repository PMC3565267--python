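"""Domain types and periodic geometry for tangent hard-sphere chain systems.

The model is the freely-jointed chain of tangent hard spheres: monomers are
non-overlapping spheres of diameter ``sigma`` and consecutive spheres along a
chain are bonded at a length equal to the diameter, imposed within a small
tolerance ``l in [sigma, sigma + tangency_tol]``.  There are no bending or
torsion potentials, so the only interactions are hard-core exclusion and the
tangency constraint; temperature is irrelevant (athermal system) and every
phase transition is entropy-driven.

Internally the unit of length is the sphere diameter, ``sigma = 1``.  All
coordinates are stored wrapped into ``[0, L)`` of a periodic box.  Simulation
cells are cubic; orthorhombic boxes are admitted for crystal fixtures whose
exact periodic cell cannot be cubic (close-packed stackings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

SIGMA = 1.0
#: slack absorbing floating-point round-off in wrapped coordinates; a
#: non-bonded pair is only reported as overlapping below ``sigma - EPS_NUM``.
EPS_NUM = 1e-12
DEFAULT_TANGENCY_TOL = 1e-8


class ConfigurationError(ValueError):
    """Raised for malformed boxes, topologies, or inconsistent inputs."""


class SimulationBox:
    """Periodic simulation cell.

    Constructed from a single edge length (cubic, the case of every actual
    simulation) or three edge lengths (orthorhombic, used only by crystal
    fixtures whose exact periodic cell is not cubic).
    """

    __slots__ = ("edge_lengths",)

    def __init__(self, edge_lengths: float | np.ndarray) -> None:
        e = np.atleast_1d(np.asarray(edge_lengths, dtype=float))
        if e.size == 1:
            e = np.repeat(e, 3)
        if e.shape != (3,) or not np.all(np.isfinite(e)) or np.any(e <= 2 * SIGMA):
            raise ConfigurationError(
                f"edge lengths must be finite and > 2*sigma, got {edge_lengths!r}"
            )
        self.edge_lengths = e
        self.edge_lengths.flags.writeable = False

    @property
    def is_cubic(self) -> bool:
        e = self.edge_lengths
        return bool(np.all(np.abs(e - e[0]) < 1e-12 * e[0]))

    @property
    def edge_length(self) -> float:
        """Edge of a cubic box; error for orthorhombic cells."""
        if not self.is_cubic:
            raise ConfigurationError("box is not cubic")
        return float(self.edge_lengths[0])

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap coordinates into ``[0, L)`` per axis."""
        return np.mod(positions, self.edge_lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SimulationBox({self.edge_lengths.tolist()})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SimulationBox) and np.array_equal(
            self.edge_lengths, other.edge_lengths
        )


def minimum_image_displacement(
    p: np.ndarray, q: np.ndarray, box: SimulationBox
) -> np.ndarray:
    """Shortest periodic displacement from ``p`` to ``q``.

    Each component of the result lies in ``(-L/2, L/2]``.  Both arguments may
    be single coordinates or arrays broadcastable against each other.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ConfigurationError("coordinates must be finite")
    L = box.edge_lengths
    d = q - p
    return d - L * np.ceil(d / L - 0.5)


def minimum_image_distance(p: np.ndarray, q: np.ndarray, box: SimulationBox) -> np.ndarray:
    d = minimum_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass(frozen=True)
class EnsembleSpec:
    """Chain-length ensemble of the n_at n_ch V T mu formulation.

    Chain-connectivity-altering moves exchange monomers between chains, so
    individual chain lengths fluctuate while ``n_at`` and ``n_ch`` are
    conserved.  The length distribution is controlled by relative chemical
    potentials ``mu*`` per species (chain length); this spec only fixes the
    *target* distribution, the engine solves the ``mu*`` profile on the fly.

    distribution:
        ``uniform`` — lengths confined to ``[N_av(1-delta), N_av(1+delta)]``.
        ``flory``   — most-probable distribution ``P(N) ∝ p^(N - N_min)`` with
        a hard minimum length ``N_min``; ``p`` is set so the mean is ``N_av``.
    """

    distribution: str = "uniform"
    n_av: float = 12.0
    delta: float = 0.5
    n_min: int = 3
    #: per-length relative chemical potentials (flat if None); the athermal
    #: temperature is a placeholder and never enters any acceptance rule.
    chemical_potentials: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "flory"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "uniform":
            lo, hi = self.length_range()
            if lo < 1 or hi < lo:
                raise ConfigurationError("empty uniform length interval")
        elif self.n_min < 1 or self.n_av <= self.n_min:
            raise ConfigurationError("flory requires n_av > n_min >= 1")

    def length_range(self) -> tuple[int, int]:
        """Allowed (inclusive) chain-length interval."""
        if self.distribution == "uniform":
            lo = int(math.ceil(self.n_av * (1.0 - self.delta) - 1e-9))
            hi = int(math.floor(self.n_av * (1.0 + self.delta) + 1e-9))
            return max(lo, 1), hi
        # Flory: open-ended above; cap far in the tail for practical sampling
        mean_excess = self.n_av - self.n_min
        return self.n_min, int(self.n_min + max(10.0 * mean_excess, 20.0))

    def target_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Lengths and normalized target probabilities over length_range."""
        lo, hi = self.length_range()
        lengths = np.arange(lo, hi + 1)
        if self.distribution == "uniform":
            probs = np.full(lengths.size, 1.0 / lengths.size)
        else:
            # geometric with mean n_av:  mean = n_min + p/(1-p)
            p = (self.n_av - self.n_min) / (self.n_av - self.n_min + 1.0)
            probs = p ** (lengths - self.n_min)
            probs = probs / probs.sum()
        return lengths, probs

    def sample_length(self, rng: np.random.Generator) -> int:
        lengths, probs = self.target_pmf()
        return int(rng.choice(lengths, p=probs))


@dataclass
class ValidityReport:
    """Report-only validity check result; empty lists iff invariants hold."""

    overlaps: list[tuple[int, int, float]] = field(default_factory=list)
    bond_violations: list[tuple[int, int, float]] = field(default_factory=list)
    partition_defects: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.overlaps or self.bond_violations or self.partition_defects)

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.ok:
            return "valid"
        return (
            f"{len(self.overlaps)} overlap(s), "
            f"{len(self.bond_violations)} bond violation(s), "
            f"{len(self.partition_defects)} partition defect(s)"
        )


class ChainSystem:
    """State of a packing of freely-jointed tangent hard-sphere chains.

    Parameters
    ----------
    positions : (n_at, 3) array
        Sphere centers in units of sigma; wrapped into the box on input.
    chains : sequence of int sequences
        Ordered partition of site indices into chains; consecutive indices
        within a chain are bonded.  Chains of length 1 (monomer mode) carry
        no bonds.
    box : SimulationBox
    tangency_tol : float
        Allowed bond-length excess above sigma.
    """

    def __init__(
        self,
        positions: np.ndarray,
        chains: list[np.ndarray] | list[list[int]],
        box: SimulationBox,
        tangency_tol: float = DEFAULT_TANGENCY_TOL,
    ) -> None:
        self.box = box
        self.positions = box.wrap(np.asarray(positions, dtype=float).reshape(-1, 3))
        self.chains = [np.asarray(c, dtype=np.int64).ravel() for c in chains]
        self.tangency_tol = float(tangency_tol)
        self.diameter = SIGMA

    # -- derived topology ---------------------------------------------------

    @property
    def n_at(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ch(self) -> int:
        return len(self.chains)

    @property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) consecutive-pair index array."""
        pairs = [
            np.column_stack([c[:-1], c[1:]]) for c in self.chains if c.size > 1
        ]
        if not pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(pairs, axis=0)

    def chain_ids(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (chain_id, index_in_chain) arrays; -1 for orphan sites."""
        cid = np.full(self.n_at, -1, dtype=np.int64)
        idx = np.full(self.n_at, -1, dtype=np.int64)
        for i, c in enumerate(self.chains):
            cid[c] = i
            idx[c] = np.arange(c.size)
        return cid, idx

    def chain_lengths(self) -> np.ndarray:
        return np.array([c.size for c in self.chains], dtype=np.int64)

    def copy(self) -> "ChainSystem":
        return ChainSystem(
            self.positions.copy(),
            [c.copy() for c in self.chains],
            self.box,
            self.tangency_tol,
        )

    # -- geometry -----------------------------------------------------------

    def unwrapped_chain(self, chain_index: int) -> np.ndarray:
        """Chain coordinates unwrapped by following bonds from the first sphere."""
        c = self.chains[chain_index]
        out = np.empty((c.size, 3))
        out[0] = self.positions[c[0]]
        for k in range(1, c.size):
            step = minimum_image_displacement(
                self.positions[c[k - 1]], self.positions[c[k]], self.box
            )
            out[k] = out[k - 1] + step
        return out


def packing_fraction(system: ChainSystem) -> float:
    """Volume fraction phi = n_at * (pi/6) * sigma^3 / V."""
    return system.n_at * (math.pi / 6.0) * SIGMA**3 / system.box.volume


def box_for_phi(n_at: int, phi: float) -> SimulationBox:
    """Cubic box realizing packing fraction ``phi`` for ``n_at`` spheres."""
    if not 0.0 < phi <= 1.0:
        raise ConfigurationError(f"phi must be in (0, 1], got {phi}")
    L = (n_at * (math.pi / 6.0) / phi) ** (1.0 / 3.0)
    return SimulationBox(L)


def validate(system: ChainSystem) -> ValidityReport:
    """Check all hard constraints; report-only, never raises on violations.

    Lists every overlapping non-bonded pair (minimum-image distance below
    ``sigma - EPS_NUM``), every bond outside ``[sigma, sigma + tangency_tol]``
    (bonded pairs obey the same hard lower bound sigma), and every defect of
    the chain partition (duplicate or missing sites).
    """
    report = ValidityReport()
    n = system.n_at

    seen = np.zeros(n, dtype=np.int64)
    for ci, c in enumerate(system.chains):
        if c.size == 0:
            report.partition_defects.append(f"chain {ci} is empty")
            continue
        if np.any(c < 0) or np.any(c >= n):
            report.partition_defects.append(f"chain {ci} has out-of-range site index")
            continue
        np.add.at(seen, c, 1)
    for site in np.nonzero(seen > 1)[0]:
        report.partition_defects.append(f"site {site} belongs to {seen[site]} chains")
    for site in np.nonzero(seen == 0)[0]:
        report.partition_defects.append(f"site {site} belongs to no chain")

    bonds = system.bonds
    bond_set = set()
    if bonds.size:
        lengths = minimum_image_distance(
            system.positions[bonds[:, 0]], system.positions[bonds[:, 1]], system.box
        )
        bad = (lengths < SIGMA - EPS_NUM) | (lengths > SIGMA + system.tangency_tol)
        for (i, j), l in zip(bonds[bad], lengths[bad]):
            report.bond_violations.append((int(i), int(j), float(l)))
        bond_set = {(min(i, j), max(i, j)) for i, j in bonds}

    if n >= 2:
        tree = cKDTree(system.positions, boxsize=system.box.edge_lengths)
        for i, j in tree.query_pairs(r=SIGMA - EPS_NUM):
            if (min(i, j), max(i, j)) in bond_set:
                continue  # bonded pairs are judged by the bond rule above
            d = float(
                minimum_image_distance(
                    system.positions[i], system.positions[j], system.box
                )
            )
            if d < SIGMA - EPS_NUM:
                report.overlaps.append((int(i), int(j), d))

    return report
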