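"""Unit-sphere tessellations, gradient schemes and angular arithmetic.

Direction sets here carry *line* (antipodally symmetric) semantics: a fiber
population along ``v`` is indistinguishable from one along ``-v``.  Hemisphere
tessellations therefore keep exactly one representative per antipodal pair,
with a fixed tie-break so that peak indices are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Tessellation",
    "icosphere",
    "angle_between_lines",
    "gradient_scheme_81",
    "save_directions",
    "load_directions",
]

_MAX_SUBDIVISIONS = 7
_ANTIPODAL_TOL = 1e-6


@dataclass(frozen=True)
class Tessellation:
    """A set of unit directions with neighbor structure.

    Parameters
    ----------
    vertices : (N, 3) float array
        Unit vectors.
    hemisphere : bool
        True when antipodal duplicates have been removed.
    adjacency : tuple of int arrays
        ``adjacency[i]`` lists the vertices sharing a mesh edge with vertex
        ``i`` (or, for non-mesh direction sets, its nearest neighbors by line
        angle).  Symmetric: ``j in adjacency[i]  <=>  i in adjacency[j]``.
    """

    vertices: np.ndarray
    hemisphere: bool
    adjacency: tuple = field(default=(), compare=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tessellation vertices must have unit norm")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    def mirrored(self) -> np.ndarray:
        """Union of the vertices with their negations (full-sphere cloud)."""
        return np.vstack([self.vertices, -self.vertices])


# ---------------------------------------------------------------------------
# icosahedron subdivision
# ---------------------------------------------------------------------------

def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def _subdivide(verts, faces):
    """Split every triangle into 4, projecting edge midpoints to the sphere."""
    verts = list(map(tuple, verts))
    midpoint_cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key in midpoint_cache:
            return midpoint_cache[key]
        m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
        m /= np.linalg.norm(m)
        verts.append(tuple(m))
        idx = len(verts) - 1
        midpoint_cache[key] = idx
        return idx

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=int)


def _keep_representative(v, tol=_ANTIPODAL_TOL):
    """Hemisphere tie-break: keep nonnegative z, then y, then x."""
    if v[2] > tol:
        return True
    if v[2] < -tol:
        return False
    if v[1] > tol:
        return True
    if v[1] < -tol:
        return False
    return v[0] >= -tol


def _adjacency_from_faces(n_vertices, faces):
    neighbor_sets = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        neighbor_sets[a].update((b, c))
        neighbor_sets[b].update((a, c))
        neighbor_sets[c].update((a, b))
    return neighbor_sets


def icosphere(subdivisions: int, hemisphere: bool = False) -> Tessellation:
    """Tessellate the sphere by recursive icosahedron subdivision.

    The full sphere has ``10 * 4**subdivisions + 2`` vertices; the hemisphere
    variant keeps one vertex per antipodal pair (``(n + something)/2``; e.g.
    321 at three subdivisions), with edge adjacency folded through the
    antipodal identification.

    Parameters
    ----------
    subdivisions : int
        Number of recursive 4-way triangle splits, ``0 <= subdivisions <= 7``.
    hemisphere : bool
        Drop antipodal duplicates (line semantics).
    """
    if not 0 <= subdivisions <= _MAX_SUBDIVISIONS:
        raise ValueError(
            f"subdivisions must be in [0, {_MAX_SUBDIVISIONS}], got {subdivisions}"
        )
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    neighbor_sets = _adjacency_from_faces(len(verts), faces)

    if not hemisphere:
        adjacency = tuple(np.array(sorted(s), dtype=int) for s in neighbor_sets)
        return Tessellation(verts, hemisphere=False, adjacency=adjacency)

    keep = np.array([_keep_representative(v) for v in verts])
    # pair every dropped vertex with its kept antipode
    kept_idx = np.flatnonzero(keep)
    new_index = -np.ones(len(verts), dtype=int)
    new_index[kept_idx] = np.arange(len(kept_idx))
    dropped = np.flatnonzero(~keep)
    if len(dropped):
        kept_verts = verts[kept_idx]
        # antipode of a dropped vertex is a kept vertex (exact by construction)
        d = -verts[dropped] @ kept_verts.T
        partner = np.argmin(1.0 - d, axis=1)
        new_index[dropped] = partner
    folded = [set() for _ in kept_idx]
    for i, s in enumerate(neighbor_sets):
        ni = new_index[i]
        for j in s:
            nj = new_index[j]
            if ni != nj:
                folded[ni].add(nj) if keep[i] else folded[nj].add(ni)
    # symmetrize (folding can be one-sided at the equator seam)
    for i, s in enumerate(folded):
        for j in s:
            folded[j].add(i)
    adjacency = tuple(np.array(sorted(s), dtype=int) for s in folded)
    return Tessellation(verts[kept_idx], hemisphere=True, adjacency=adjacency)


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def angle_between_lines(a, b) -> float:
    """Angle in degrees, in [0, 90], between the *lines* spanned by a and b.

    Antipodally symmetric: flipping the sign of either argument leaves the
    result unchanged.  Accepts arrays broadcastable along the last axis.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("angle_between_lines requires nonzero vectors")
    cosang = np.abs(np.sum(a * b, axis=-1)) / (na * nb)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def min_pairwise_line_angle(directions) -> float:
    """Smallest line angle over all distinct pairs of a direction set."""
    d = np.asarray(directions, dtype=float)
    g = np.abs(d @ d.T)
    np.fill_diagonal(g, 0.0)
    return float(np.degrees(np.arccos(np.clip(g.max(), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# 81-direction acquisition scheme
# ---------------------------------------------------------------------------

def generate_repulsion_scheme(n: int, seed: int = 20170, n_iter: int = 4000,
                              step: float = 5e-3) -> np.ndarray:
    """Electrostatic-repulsion minimization of n hemisphere points.

    Minimizes the antipodally symmetrized Coulomb energy
    ``sum_{i<j} 1/|x_i - x_j|^2 + 1/|x_i + x_j|^2`` by projected gradient
    descent from a seeded random start.  Deterministic given (n, seed).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]   # x_i - (+-x_j)
            d2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if sign < 0:
                d2[d2 < 1e-12] = np.inf  # i==j antipodal self-term
            force += np.sum(diff / (d2 * d2)[..., None], axis=1)
        # project the force onto the tangent plane; clip displacements so a
        # near-collision (huge force) cannot overshoot through its neighbor
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        disp = step * force
        norm = np.linalg.norm(disp, axis=1, keepdims=True)
        disp *= np.minimum(1.0, 0.02 / np.maximum(norm, 1e-30))
        x = x + disp
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere representatives, stable ordering
    x = np.array([v if _keep_representative(v) else -v for v in x])
    order = np.lexsort((x[:, 0], x[:, 1], x[:, 2]))
    return x[order]


def gradient_scheme_81() -> np.ndarray:
    """The packaged 81-direction single-shell sampling scheme.

    Quasi-uniform hemisphere directions produced once by electrostatic
    repulsion (`generate_repulsion_scheme`) and shipped as a text asset so
    the scheme is bit-identical across platforms and runs.
    """
    with resources.files("irlfod.data").joinpath("scheme81.txt").open("r") as fh:
        d = np.loadtxt(fh)
    return d


def knn_adjacency(directions, k: int = 6) -> tuple:
    """Symmetrized k-nearest-neighbor adjacency by line angle."""
    d = np.asarray(directions, dtype=float)
    g = np.abs(d @ d.T)
    np.fill_diagonal(g, -1.0)
    nn = np.argsort(-g, axis=1)[:, :k]
    sets = [set(row) for row in nn]
    for i, s in enumerate(list(sets)):
        for j in s:
            sets[j].add(i)
    return tuple(np.array(sorted(s), dtype=int) for s in sets)


def save_directions(path, directions) -> None:
    """Write one unit vector per row, whitespace-delimited (bvecs-transposed)."""
    np.savetxt(path, np.asarray(directions, dtype=float), fmt="%+.17e")


def load_directions(path) -> np.ndarray:
    d = np.loadtxt(path)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("direction file must have 3 columns")
    return d
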