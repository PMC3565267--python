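"""Periodic Voronoi tessellation and inertia-tensor shape analysis of cells.

Each sphere's local environment is the Voronoi polyhedron of its site — the
region closer to it than to any other site.  The tessellation is space
filling, so the mean local density (inverse cell volume) is fixed at the
global density on every frame; what changes on crystallization is the
*shape* of the cells.  Shape is quantified through the inertia tensor of the
cell's vertices, treated as equivalent unit point masses:

    I = (1/n_ver) * sum_i ( |r_i|^2 delta - r_i r_i^T )

with r_i measured from the vertex centroid, eigenvalues I1 >= I2 >= I3.  A
coarse-grained ellipsoid has semiaxes L1 = sqrt((5/2)(I2+I3-I1)) (cyclic),
and the global shape measures are

    asphericity               b  = (I1+I2)/2 - I3
    acylindricity             c  = I1 - I2
    relative shape anisotropy k2 = 4(1 - 3(I1 I2 + I2 I3 + I3 I1)/(I1+I2+I3)^2)

all zero for fully symmetric cells and positive otherwise (k2 <= 1, equal to
1 in the collinear limit).  The reference cells are the rhombic dodecahedron
(fcc) and the trapezo-rhombic dodecahedron (hcp).  Note that both *ideal*
cells have exactly isotropic vertex inertia (b = c = k2 = 0): the hcp cell
is the fcc cell with its lower half rotated 60 degrees about the threefold
axis, and each half's inertia is transversely isotropic about that axis, so
the rotation changes nothing.  The b asymmetry seen between hcp-like and
fcc-like sites in simulations is a property of thermally distorted cells,
not of the ideal polyhedra; c = 0 remains exact for the ideal hcp cell.

Vertex coordinates are in units of sigma, so b and c carry units of sigma^2;
the scale constant ``LENGTH_UNIT`` isolates this convention.

The periodic tessellation augments the box with ghost images (the 26
neighbouring translates, pruned to a shell) and keeps the cells of primary
sites, using Qhull via scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, Voronoi

from .core import ChainSystem

#: unit of length for vertex coordinates entering the inertia tensor (sigma)
LENGTH_UNIT = 1.0

#: merge tolerance for coincident polyhedron vertices produced by degenerate
#: (cospherical) site configurations such as perfect lattices
VERTEX_MERGE_TOL = 1e-6


@dataclass
class VoronoiCell:
    """One site's Voronoi polyhedron.

    ``vertices`` are raw Qhull vertices relative to the site position;
    ``unique_vertices`` merges coincident vertices (degenerate tessellations
    split high-order vertices into clusters) and is what the shape analysis
    consumes.  ``faces`` index into ``vertices``; ``neighbor_ids`` gives the
    site sharing each face.
    """

    site_id: int
    vertices: np.ndarray  # (n_ver, 3), relative to the site position
    faces: list[list[int]]
    neighbor_ids: list[int]
    volume: float

    @property
    def unique_vertices(self) -> np.ndarray:
        v = self.vertices
        scale = max(np.max(np.abs(v)), 1.0)
        keys = np.round(v / (VERTEX_MERGE_TOL * scale)).astype(np.int64)
        _, first, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
        merged = np.zeros((first.size, 3))
        counts = np.zeros(first.size)
        np.add.at(merged, inv, v)
        np.add.at(counts, inv, 1.0)
        return merged / counts[:, None]


def tessellate(
    system: ChainSystem,
    shell_width: float | None = None,
    _jitter: float = 0.0,
) -> list[VoronoiCell]:
    """Periodic Voronoi tessellation; one closed convex cell per site.

    Cells tile the box (volumes sum to V) and the face-neighbour relation is
    symmetric.  Degenerate cospherical configurations that Qhull rejects are
    retried once with a reported 1e-10 sigma jitter.
    """
    pos = system.positions
    n = system.n_at
    if n < 2:
        raise ValueError("tessellation needs at least 2 sites")
    L = system.box.edge_lengths

    if shell_width is None:
        # generous bound on cell extent; fall back to full images when the
        # box is small
        shell_width = 4.0 * (system.box.volume / n) ** (1.0 / 3.0)
    shell_width = float(min(shell_width, np.min(L)))

    base = pos if _jitter == 0.0 else system.box.wrap(
        pos + np.random.default_rng(0).uniform(-_jitter, _jitter, pos.shape)
    )
    points = [base]
    orig = [np.arange(n)]
    for shift in np.ndindex(3, 3, 3):
        off = (np.array(shift) - 1) * L
        if not np.any(off):
            continue
        ghost = base + off
        keep = np.all(
            (ghost > -shell_width) & (ghost < L + shell_width), axis=1
        )
        if np.any(keep):
            points.append(ghost[keep])
            orig.append(np.nonzero(keep)[0])
    allpos = np.concatenate(points)
    allorig = np.concatenate(orig)

    try:
        vor = Voronoi(allpos)
        cells = _extract_cells(vor, base, allorig, n)
    except (QhullError, _OpenCellError):
        if _jitter > 0.0:
            raise
        import warnings

        warnings.warn(
            "degenerate site configuration; retrying tessellation with "
            "1e-10 sigma jitter",
            stacklevel=2,
        )
        return tessellate(system, shell_width=np.min(L), _jitter=1e-10)

    vol = sum(c.volume for c in cells)
    if not math.isclose(vol, system.box.volume, rel_tol=1e-8):
        if shell_width < np.min(L):  # pruned too aggressively; use all images
            return tessellate(system, shell_width=np.min(L), _jitter=_jitter)
        raise RuntimeError(
            f"tessellation does not tile the box: {vol} != {system.box.volume}"
        )
    return cells


class _OpenCellError(RuntimeError):
    pass


def _extract_cells(
    vor: Voronoi, base: np.ndarray, allorig: np.ndarray, n: int
) -> list[VoronoiCell]:
    # face lists per primary site from the ridge table
    faces: list[list[list[int]]] = [[] for _ in range(n)]
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        for a, b in ((p, q), (q, p)):
            if a < n:
                if -1 in rv:
                    raise _OpenCellError("unbounded ridge on a primary cell")
                faces[a].append(list(rv))
                neighbors[a].append(int(allorig[b]))

    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 4:
            raise _OpenCellError(f"open or degenerate cell for site {i}")
        verts = vor.vertices[region]
        local = {g: k for k, g in enumerate(region)}
        face_local = [[local[g] for g in f] for f in faces[i]]
        hull = ConvexHull(verts)
        cells.append(
            VoronoiCell(
                site_id=i,
                vertices=verts - base[i],
                faces=face_local,
                neighbor_ids=neighbors[i],
                volume=float(hull.volume),
            )
        )
    return cells


@dataclass(frozen=True)
class ShapeMeasures:
    """Inertia eigensystem and global shape measures of one cell."""

    I1: float
    I2: float
    I3: float
    L1: float
    L2: float
    L3: float
    b: float
    c: float
    k2: float
    volume: float
    local_density: float


def inertia_tensor(cell: VoronoiCell) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertex-mass inertia tensor, eigenvalues (descending), eigenvectors.

    All merged vertices are equivalent unit point masses; positions are
    measured from the vertex centroid of the cell.
    """
    v = cell.unique_vertices
    if v.shape[0] < 4:
        raise ValueError(f"degenerate cell (fewer than 4 vertices): site {cell.site_id}")
    r = (v - v.mean(axis=0)) / LENGTH_UNIT
    r2 = np.sum(r * r, axis=1)
    tensor = (np.sum(r2) * np.eye(3) - r.T @ r) / r.shape[0]
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    order = [2, 1, 0]
    return tensor, evals[order], evecs[:, order]


def shape_measures(cell: VoronoiCell) -> ShapeMeasures:
    """Semiaxes and asphericity/acylindricity/anisotropy of one cell."""
    _, (i1, i2, i3), _ = inertia_tensor(cell)
    tr = i1 + i2 + i3
    if tr <= 0.0:
        raise ValueError(f"all vertices coincide for site {cell.site_id}")
    l1 = math.sqrt(max(2.5 * (i2 + i3 - i1), 0.0))
    l2 = math.sqrt(max(2.5 * (i3 + i1 - i2), 0.0))
    l3 = math.sqrt(max(2.5 * (i1 + i2 - i3), 0.0))
    b = 0.5 * (i1 + i2) - i3
    c = i1 - i2
    k2 = 4.0 * (1.0 - 3.0 * (i1 * i2 + i2 * i3 + i3 * i1) / tr**2)
    return ShapeMeasures(
        I1=i1,
        I2=i2,
        I3=i3,
        L1=l1,
        L2=l2,
        L3=l3,
        b=b,
        c=c,
        k2=min(max(k2, 0.0), 1.0),
        volume=cell.volume,
        local_density=1.0 / cell.volume,
    )


def frame_shape_table(system: ChainSystem):
    """Per-site tidy table of cell shape measures for one configuration."""
    import pandas as pd

    cid, _ = system.chain_ids()
    cells = tessellate(system)
    rows = []
    for cell in cells:
        m = shape_measures(cell)
        rows.append(
            {
                "site_id": cell.site_id,
                "chain_id": cid[cell.site_id],
                "volume": m.volume,
                "local_density": m.local_density,
                "I1": m.I1,
                "I2": m.I2,
                "I3": m.I3,
                "L1": m.L1,
                "L2": m.L2,
                "L3": m.L3,
                "b": m.b,
                "c": m.c,
                "k2": m.k2,
                "n_faces": len(cell.faces),
            }
        )
    return pd.DataFrame(rows)


def shape_profile(trajectory) -> "pd.DataFrame":  # noqa: F821
    """Per-frame means of b, c, k2 (and density book-keeping) over all cells."""
    import pandas as pd

    rows = []
    for f, system in enumerate(trajectory):
        cells = tessellate(system)
        ms = [shape_measures(c) for c in cells]
        rows.append(
            {
                "frame": f,
                "mean_b": float(np.mean([m.b for m in ms])),
                "mean_c": float(np.mean([m.c for m in ms])),
                "mean_k2": float(np.mean([m.k2 for m in ms])),
                "mean_volume": float(np.mean([m.volume for m in ms])),
                # space-filling identity: total spheres over total cell
                # volume; exactly the global density on every frame
                "mean_local_density": len(cells) / float(
                    np.sum([m.volume for m in ms])
                ),
            }
        )
    return pd.DataFrame(rows)
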