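"""Ground-truth crystal fixtures and dilute chain generators.

Close-packed crystals of equal spheres are stackings of triangular layers in
the three lateral registries A, B, C (adjacent layers must differ).  Pure
``ABAB`` repetition is hcp, pure ``ABCABC`` repetition is fcc, and a random
admissible letter sequence is an rhcp (randomly stacked hexagonal close
packing) — the morphology dense hard-sphere systems actually self-assemble
into.  A site's local character is fixed combinatorially by its two flanking
layers: same letter → hcp-like, different letters → fcc-like.

These generators provide defect-free reference lattices with known per-site
labels, ideal 12-vector first-shell templates for the three competing local
symmetries (hcp, fcc, fivefold/icosahedral), and dilute tangent random-walk
chain configurations used to seed compression runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    SIGMA,
    ChainSystem,
    ConfigurationError,
    EnsembleSpec,
    SimulationBox,
    box_for_phi,
    minimum_image_displacement,
)

#: inter-layer spacing of close-packed triangular layers at contact, in sigma
LAYER_SPACING = math.sqrt(2.0 / 3.0)

#: lateral registry offsets of the three stacking positions, in sigma
_OFFSETS = {
    "A": np.array([0.0, 0.0]),
    "B": np.array([0.5, 0.5 / math.sqrt(3.0)]),
    "C": np.array([0.0, 1.0 / math.sqrt(3.0)]),
}


@dataclass(frozen=True)
class StackingSequence:
    """A close-packed stacking: letters over {A,B,C}, adjacent letters differ."""

    layers: str
    n_per_layer: tuple[int, int] = (4, 4)  # (nx, ny) triangular-lattice tile

    def __post_init__(self) -> None:
        if len(self.layers) < 3:
            raise ConfigurationError("stacking needs at least 3 layers")
        if any(ch not in "ABC" for ch in self.layers):
            raise ConfigurationError("stacking letters must be A, B or C")
        if any(a == b for a, b in zip(self.layers, self.layers[1:])):
            raise ConfigurationError("adjacent stacking letters must differ")
        nx, ny = self.n_per_layer
        if nx < 2 or ny < 2 or ny % 2:
            raise ConfigurationError("layer tile needs nx >= 2 and even ny >= 2")

    @property
    def wraps(self) -> bool:
        """True when the sequence is admissible across the periodic z boundary."""
        return self.layers[0] != self.layers[-1]


def random_stacking(
    n_layers: int, rng: np.random.Generator, n_per_layer: tuple[int, int] = (4, 4)
) -> StackingSequence:
    """Uniformly random admissible stacking sequence."""
    letters = [rng.choice(list("ABC"))]
    for _ in range(n_layers - 1):
        letters.append(rng.choice([c for c in "ABC" if c != letters[-1]]))
    return StackingSequence("".join(letters), n_per_layer)


def make_stacking(seq: StackingSequence, spacing: float = SIGMA) -> ChainSystem:
    """Build the close-packed stacking as a monomeric ChainSystem.

    Layers are triangular lattices at nearest-neighbour distance ``spacing``,
    periodic in-plane on an orthorhombic-commensurate tile so every in-layer
    first shell is exact.  If the sequence is admissible across the z
    boundary the cell is fully periodic at contact; otherwise one extra layer
    spacing of vacuum is inserted so the terminal layers never touch their
    periodic images (they are surface/"boundary" layers).
    """
    nx, ny = seq.n_per_layer
    n_layers = len(seq.layers)
    a = spacing
    Lx, Ly = nx * a, ny * a * math.sqrt(3.0) / 2.0
    h = a * LAYER_SPACING
    Lz = n_layers * h if seq.wraps else (n_layers + 1) * h

    # one triangular layer on the rectangular tile
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    base = np.column_stack(
        [
            (i + 0.5 * (j % 2)).ravel() * a,
            j.ravel() * a * math.sqrt(3.0) / 2.0,
        ]
    )

    frames = []
    for k, letter in enumerate(seq.layers):
        xy = base + _OFFSETS[letter] * a
        layer = np.column_stack([xy, np.full(len(xy), k * h)])
        frames.append(layer)
    positions = np.concatenate(frames, axis=0)

    box = SimulationBox(np.array([Lx, Ly, Lz]))
    chains = [np.array([s]) for s in range(len(positions))]
    return ChainSystem(positions, chains, box)


def stacking_ground_truth(seq: StackingSequence) -> list[str]:
    """Per-layer label from the flanking-layer rule.

    An interior layer is hcp-like when its two flanking layers carry the same
    letter (locally ...X Y X...) and fcc-like when they differ; terminal
    layers have only one flank and are labelled ``boundary``.
    """
    labels = ["boundary"]
    for k in range(1, len(seq.layers) - 1):
        same = seq.layers[k - 1] == seq.layers[k + 1]
        labels.append("hcp" if same else "fcc")
    labels.append("boundary")
    return labels


def stacking_site_labels(seq: StackingSequence) -> np.ndarray:
    """Per-site labels matching ``make_stacking`` site order."""
    per_layer = stacking_ground_truth(seq)
    nx, ny = seq.n_per_layer
    return np.repeat(np.array(per_layer, dtype=object), nx * ny)


def make_fcc(n_cells: int = 3, spacing: float = SIGMA) -> ChainSystem:
    """Periodic fcc crystal at contact in its cubic conventional cell.

    ``n_cells`` conventional cells per axis, 4 sites per cell, lattice
    constant ``spacing * sqrt(2)``; every site has an exact 12-neighbour
    first shell at distance ``spacing`` and the cell is cubic-commensurate,
    so the packing fraction is exactly pi/sqrt(18).
    """
    a = spacing * math.sqrt(2.0)
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    )
    cells = np.stack(
        np.meshgrid(*[np.arange(n_cells)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    positions = ((cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)) * a
    box = SimulationBox(n_cells * a)
    chains = [np.array([s]) for s in range(len(positions))]
    return ChainSystem(positions, chains, box)


def make_hcp(n_layers: int = 4, n_per_layer: tuple[int, int] = (4, 4)) -> ChainSystem:
    """Fully periodic hcp crystal (pure AB stacking) at contact."""
    if n_layers % 2:
        raise ConfigurationError("periodic hcp needs an even layer count")
    return make_stacking(StackingSequence("AB" * (n_layers // 2), n_per_layer))


# ---------------------------------------------------------------------------
# ideal first-shell templates


@dataclass(frozen=True)
class CoordinationTemplate:
    """Ideal first coordination shell of a reference local structure.

    ``unit_vectors`` are the 12 directions from a central site to its ideal
    neighbours; ``symmetry_ops`` are the distinguishing point-symmetry
    operations of the structure — orthogonal matrices that map the ideal
    shell onto itself but are absent from the competing structures (the
    four-fold rotation of fcc, the horizontal mirror of hcp, the five-fold
    rotation of the icosahedral motif).  The classification norm penalizes a
    shell's self-mismatch under these operations, which is what separates
    structures whose raw direction sets are geometrically close.
    """

    name: str
    unit_vectors: np.ndarray  # (12, 3), unit norm
    symmetry_ops: tuple[np.ndarray, ...]

    @property
    def n_directions(self) -> int:
        return self.unit_vectors.shape[0]


def _shell_cp(bottom_azimuths_deg: tuple[float, float, float]) -> np.ndarray:
    """12-vector close-packed shell: 6 in-plane, 3 up at 30/150/270 degrees,
    3 down at the given azimuths (eclipsed 30/150/270 → hcp, staggered
    90/210/330 → fcc)."""
    vecs = []
    for az in range(0, 360, 60):
        t = math.radians(az)
        vecs.append([math.cos(t), math.sin(t), 0.0])
    z = LAYER_SPACING
    r = 1.0 / math.sqrt(3.0)
    for az in (30.0, 150.0, 270.0):
        t = math.radians(az)
        vecs.append([r * math.cos(t), r * math.sin(t), z])
    for az in bottom_azimuths_deg:
        t = math.radians(az)
        vecs.append([r * math.cos(t), r * math.sin(t), -z])
    return np.array(vecs)


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_SIGMA_H = np.diag([1.0, 1.0, -1.0])


def _c2_inplane(deg: float) -> np.ndarray:
    """Two-fold rotation about an in-plane axis at the given azimuth."""
    t = math.radians(deg)
    u = np.array([math.cos(t), math.sin(t), 0.0])
    return 2.0 * np.outer(u, u) - np.eye(3)


def _rot_axis(axis: tuple[float, float, float], deg: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a /= np.linalg.norm(a)
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(a, a)


def _s6_axis(axis: tuple[float, float, float]) -> np.ndarray:
    """Roto-reflection by 60 degrees about the given axis."""
    a = np.asarray(axis, dtype=float)
    a /= np.linalg.norm(a)
    mirror = np.eye(3) - 2.0 * np.outer(a, a)
    return _rot_axis(tuple(a), 60.0) @ mirror


def _icosahedral_shell() -> np.ndarray:
    """Icosahedron vertices with a five-fold axis along z."""
    vecs = [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]
    theta = math.atan2(2.0, 1.0)  # polar angle of the upper ring
    for k in range(5):
        az = 2.0 * math.pi * k / 5.0
        vecs.append(
            [math.sin(theta) * math.cos(az), math.sin(theta) * math.sin(az), math.cos(theta)]
        )
        az2 = az + math.pi / 5.0
        vecs.append(
            [
                math.sin(theta) * math.cos(az2),
                math.sin(theta) * math.sin(az2),
                -math.cos(theta),
            ]
        )
    return np.array(vecs)


def _pentagonal_bipyramid_shell() -> np.ndarray:
    """7-vector fivefold motif: equatorial pentagon plus two apices."""
    vecs = [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]
    for k in range(5):
        az = 2.0 * math.pi * k / 5.0
        vecs.append([math.cos(az), math.sin(az), 0.0])
    return np.array(vecs)


def make_template(name: str) -> CoordinationTemplate:
    """Ideal first-shell template for ``hcp``, ``fcc`` or ``fivefold``.

    fcc is the cuboctahedral shell (given in its cubic orientation), hcp the
    triangular-orthobicupola (anticuboctahedral) shell with the stacking axis
    along z, fivefold the icosahedral shell with a five-fold axis along z
    (the 7-site pentagonal-bipyramid motif is available as ``fivefold7``).
    The classification norm is rotation-invariant so the orientation of each
    template is purely conventional.
    """
    if name == "fcc":
        # cuboctahedron: all permutations of (+-1, +-1, 0)/sqrt(2)
        shell = np.array(
            [
                [sx, sy, 0.0]
                for sx in (1.0, -1.0)
                for sy in (1.0, -1.0)
            ]
        )
        shell = np.concatenate([shell, shell[:, [2, 0, 1]], shell[:, [1, 2, 0]]])
        # distinguishing: two four-fold rotations (absent from hcp and
        # icosahedra) and the S6 roto-reflection about a threefold axis
        # (absent from hcp, whose stacking axis carries S3 instead)
        ops = (_rot_z(90.0), _rot_axis((1.0, 0.0, 0.0), 90.0),
               _s6_axis((1.0, 1.0, 1.0)))
    elif name == "hcp":
        shell = _shell_cp((30.0, 150.0, 270.0))
        # distinguishing D3h elements: the horizontal mirror through the
        # central layer, a two-fold axis in that mirror plane, and the S3
        # roto-reflection about the stacking axis (fcc has S6, not S3)
        ops = (_SIGMA_H, _c2_inplane(30.0), _rot_z(120.0) @ _SIGMA_H)
    elif name == "fivefold":
        shell = _icosahedral_shell()
        # five-fold rotations; no crystallographic shell admits them
        ops = (_rot_z(72.0), _rot_z(144.0))
    elif name == "fivefold7":
        shell = _pentagonal_bipyramid_shell()
        ops = (_rot_z(72.0), _rot_z(144.0))
    else:
        raise ConfigurationError(f"unknown template {name!r}")
    shell = shell / np.linalg.norm(shell, axis=1, keepdims=True)
    return CoordinationTemplate(name, shell, ops)


def template_table(template: CoordinationTemplate) -> str:
    """Plain-text unit-vector table serialization."""
    lines = [f"# coordination template: {template.name}", "# ux uy uz"]
    for v in template.unit_vectors:
        lines.append(f"{v[0]: .15f} {v[1]: .15f} {v[2]: .15f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dilute random chain configurations


class InsertionError(RuntimeError):
    """Chain growth failed; the target packing fraction is too high."""


def make_dilute_chains(
    n_ch: int,
    ensemble: EnsembleSpec,
    phi: float,
    seed: int,
    tangency_tol: float = 1e-8,
    max_site_trials: int = 200,
    max_chain_restarts: int = 50,
    exact_total: bool = True,
) -> ChainSystem:
    """Grow overlap-free tangent random walks at a dilute packing fraction.

    Chain lengths are drawn from the ensemble distribution; each chain is a
    random walk with steps of length sigma placed with hard-core rejection
    against everything already inserted.  Deterministic for a given seed.

    With ``exact_total`` (default) the sampled lengths are nudged within the
    allowed range until the total sphere count equals ``n_ch * N_av``
    exactly.  Because connectivity-altering moves conserve n_at and n_ch,
    the mean chain length is frozen at n_at/n_ch for the entire simulation;
    a configuration whose total misses ``n_ch * N_av`` could never reach a
    stationary length distribution with the requested mean.
    """
    if phi > 0.10:
        raise ConfigurationError("dilute generator is limited to phi <= 0.10")
    rng = np.random.default_rng(seed)
    lengths = [ensemble.sample_length(rng) for _ in range(n_ch)]
    if exact_total:
        lo, hi = ensemble.length_range()
        want = int(round(n_ch * ensemble.n_av))
        want = min(max(want, n_ch * lo), n_ch * hi)
        guard = 0
        while sum(lengths) != want:
            i = int(rng.integers(n_ch))
            step = 1 if sum(lengths) < want else -1
            if lo <= lengths[i] + step <= hi:
                lengths[i] += step
            guard += 1
            if guard > 100_000:
                raise ConfigurationError("cannot reach the requested total")
    n_at = int(sum(lengths))
    box = box_for_phi(n_at, phi)
    L = box.edge_lengths

    placed = np.empty((n_at, 3))
    n_placed = 0
    chains: list[np.ndarray] = []

    def clashes(p: np.ndarray, skip_last: int = 0) -> bool:
        m = n_placed - skip_last
        if m <= 0:
            return False
        d = minimum_image_displacement(placed[:m], p, box)
        return bool(np.any(np.sum(d * d, axis=1) < SIGMA**2))

    for N in lengths:
        for _restart in range(max_chain_restarts):
            start = n_placed
            ok = True
            p = rng.random(3) * L
            for t in range(max_site_trials):
                if not clashes(p):
                    break
                p = rng.random(3) * L
            else:
                ok = False
            if ok:
                placed[n_placed] = p
                n_placed += 1
                for _ in range(N - 1):
                    for t in range(max_site_trials):
                        u = rng.normal(size=3)
                        u /= np.linalg.norm(u)
                        q = box.wrap(placed[n_placed - 1] + SIGMA * u)
                        # the bonded predecessor sits exactly at distance sigma
                        if not clashes(q, skip_last=1):
                            placed[n_placed] = q
                            n_placed += 1
                            break
                    else:
                        ok = False
                        break
            if ok:
                chains.append(np.arange(start, start + N))
                break
            n_placed = start  # discard partial chain and regrow
        else:
            raise InsertionError(
                f"could not insert a chain of length {N} at phi={phi}; "
                "lower the target packing fraction"
            )

    return ChainSystem(placed, chains, box, tangency_tol=tangency_tol)
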