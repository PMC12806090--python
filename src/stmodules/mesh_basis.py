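"""Triangular mesh and piecewise-linear finite-element basis assembly.

Builds the Delaunay triangulation of the spot cloud (mesh nodes are the
spot coordinates themselves, so the basis matrix evaluated at the spots
is the identity) and assembles the mass, stiffness and curvature-penalty
matrices for linear elements.  The penalty uses the mixed formulation
``P = A M^{-1} A`` which discretizes the integrated squared Laplacian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

#: coordinates closer than this (after rounding) are considered duplicates
DUPLICATE_DECIMALS = 9

#: points this far outside the hull are snapped onto it during evaluation
SNAP_TOL = 1e-8


class MeshError(ValueError):
    """Raised for invalid spot geometry or degenerate meshes."""


@dataclass(frozen=True)
class SpotSet:
    """Spot locations ``s_j`` in the 2D tissue domain.

    Parameters
    ----------
    coords
        ``(n, 2)`` array of spatial coordinates.
    spot_ids
        Unique identifiers aligned to rows of ``coords``.
    """

    coords: np.ndarray
    spot_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise MeshError(f"coords must be (n, 2), got {coords.shape}")
        if coords.shape[0] < 3:
            raise MeshError("need at least 3 spots")
        if not np.all(np.isfinite(coords)):
            raise MeshError("non-finite coordinates")
        ids = tuple(str(s) for s in self.spot_ids)
        if len(ids) != coords.shape[0]:
            raise MeshError("spot_ids length does not match coords")
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = sorted({s for s in ids if s in seen or seen.add(s)})
            raise MeshError(f"duplicate spot_ids: {dups[:10]}")
        rounded = np.round(coords, DUPLICATE_DECIMALS)
        _, inv, counts = np.unique(
            rounded, axis=0, return_inverse=True, return_counts=True
        )
        if np.any(counts > 1):
            bad = [ids[i] for i in np.flatnonzero(counts[inv] > 1)]
            raise MeshError(f"duplicate coordinates for spots: {bad[:10]}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "spot_ids", ids)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class TriangularMesh:
    """Triangulation of the tissue domain.

    ``triangles`` are node-index triples with counterclockwise
    orientation (strictly positive signed area).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: tuple[tuple[int, int], ...]
    _delaunay: Delaunay | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        tris = np.asarray(self.triangles, dtype=int)
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise MeshError("triangles must be (T, 3)")
        if tris.min(initial=0) < 0 or tris.max(initial=-1) >= nodes.shape[0]:
            raise MeshError("triangle index out of range")
        areas = _signed_areas(nodes, tris)
        if np.any(areas <= 0):
            raise MeshError("triangle with non-positive signed area")
        used = np.zeros(nodes.shape[0], dtype=bool)
        used[tris.ravel()] = True
        if not used.all():
            raise MeshError(f"orphan nodes: {np.flatnonzero(~used)[:10].tolist()}")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "triangles", tris)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def areas(self) -> np.ndarray:
        """Signed (positive) area of every triangle."""
        return _signed_areas(self.nodes, self.triangles)

    def to_off(self) -> str:
        """OFF-style text dump (nodes then triangles) for inspection."""
        lines = ["OFF", f"{self.n_nodes} {self.n_triangles} 0"]
        lines += [f"{x:.12g} {y:.12g} 0" for x, y in self.nodes]
        lines += [f"3 {a} {b} {c}" for a, b, c in self.triangles]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BasisSystem:
    """Mesh plus the assembled FEM matrices.

    ``mass`` is the Gram matrix of the hat functions, ``stiffness`` the
    Gram matrix of their gradients, and ``penalty`` the discretized
    integrated-squared-Laplacian form ``A M^{-1} A``.
    """

    mesh: TriangularMesh
    mass: sparse.csr_matrix
    stiffness: sparse.csr_matrix
    penalty: np.ndarray

    @property
    def K(self) -> int:
        return self.mesh.n_nodes


def _signed_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def build_mesh(spots: SpotSet) -> TriangularMesh:
    """Delaunay-triangulate the spot cloud.

    Mesh nodes are exactly the spot coordinates; the domain is their
    convex hull.  All-collinear input raises :class:`MeshError`.
    """
    coords = spots.coords
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise MeshError(f"Delaunay triangulation failed (collinear input?): {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise MeshError("all spots are collinear; cannot triangulate")
    simplices = tri.simplices.copy()
    # enforce counterclockwise orientation
    areas = _signed_areas(coords, simplices)
    flip = areas < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    # canonical ordering: rotate smallest index first, sort rows
    roll = np.argmin(simplices, axis=1)
    for r in (1, 2):
        m = roll == r
        simplices[m] = np.roll(simplices[m], -r, axis=1)
    order = np.lexsort((simplices[:, 2], simplices[:, 1], simplices[:, 0]))
    simplices = simplices[order]

    hull = tri.convex_hull
    boundary = tuple(tuple(sorted(e)) for e in sorted(map(sorted, hull.tolist())))
    return TriangularMesh(
        nodes=coords, triangles=simplices, boundary_edges=boundary, _delaunay=tri
    )


def _mesh_delaunay(mesh: TriangularMesh) -> Delaunay:
    if mesh._delaunay is not None:
        return mesh._delaunay
    return Delaunay(mesh.nodes)


def evaluate_basis(mesh: TriangularMesh, points: np.ndarray) -> np.ndarray:
    """Evaluate the hat-function basis at ``points``.

    Returns an ``(m, K)`` matrix whose rows are barycentric weights of
    the containing triangle (at most 3 nonzeros, summing to one).
    Points slightly outside the hull (within :data:`SNAP_TOL`) are
    snapped; farther points raise :class:`MeshError`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise MeshError("points must be (m, 2)")
    tri = _mesh_delaunay(mesh)
    simplex = tri.find_simplex(pts)
    missing = simplex < 0
    if np.any(missing):
        # retry with tolerance: snap borderline points
        simplex2 = tri.find_simplex(pts[missing], tol=SNAP_TOL)
        still = simplex2 < 0
        if np.any(still):
            bad = np.flatnonzero(missing)[still]
            raise MeshError(f"points outside mesh: indices {bad[:10].tolist()}")
        simplex[missing] = simplex2

    X = tri.transform[simplex, :2]
    r = pts - tri.transform[simplex, 2]
    bc = np.einsum("ijk,ik->ij", X, r)
    bary = np.concatenate([bc, 1.0 - bc.sum(axis=1, keepdims=True)], axis=1)
    # clip tiny negatives from snapping, renormalize
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)

    m = pts.shape[0]
    out = np.zeros((m, mesh.n_nodes))
    cols = tri.simplices[simplex]
    np.put_along_axis(out, cols, bary, axis=1)
    return out


def _triangle_geometry(mesh: TriangularMesh) -> tuple[np.ndarray, np.ndarray]:
    """Areas and basis gradients (T, 3, 2) of all triangles."""
    nodes, tris = mesh.nodes, mesh.triangles
    areas = _signed_areas(nodes, tris)
    if np.any(areas <= 1e-14 * max(1.0, float(np.abs(nodes).max()) ** 2)):
        raise MeshError("degenerate (zero-area) triangle")
    p = nodes[tris]  # (T, 3, 2)
    # gradient of hat i on a triangle is the rotated opposite edge / (2 area)
    grads = np.empty_like(p)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        e = p[:, k] - p[:, j]
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= (2.0 * areas)[:, None, None]
    return areas, grads


_LOCAL_MASS = (np.ones((3, 3)) + np.eye(3)) / 12.0  # area-scaled local block


def assemble_mass(mesh: TriangularMesh) -> sparse.csr_matrix:
    """Consistent mass matrix ``M_jk = ∫ φ_j φ_k``."""
    areas, _ = _triangle_geometry(mesh)
    tris = mesh.triangles
    local = areas[:, None, None] * _LOCAL_MASS[None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    M = sparse.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return (M + M.T) / 2.0


def assemble_stiffness(mesh: TriangularMesh) -> sparse.csr_matrix:
    """Stiffness matrix ``A_jk = ∫ ∇φ_j · ∇φ_k``."""
    areas, grads = _triangle_geometry(mesh)
    tris = mesh.triangles
    local = np.einsum("tif,tjf->tij", grads, grads) * areas[:, None, None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    A = sparse.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return (A + A.T) / 2.0


def lump_mass(mass: sparse.spmatrix) -> sparse.csr_matrix:
    """Row-sum (diagonal) lumping of a consistent mass matrix."""
    d = np.asarray(mass.sum(axis=1)).ravel()
    return sparse.diags(d).tocsr()


def assemble_penalty(
    mass: sparse.spmatrix, stiffness: sparse.spmatrix, *, lumped: bool = False
) -> np.ndarray:
    """Curvature penalty ``P = A M^{-1} A`` (dense ``K×K``).

    ``lumped=True`` replaces the consistent mass by its diagonal lumping,
    trading a little accuracy for a much cheaper solve.
    """
    K = mass.shape[0]
    if stiffness.shape != (K, K):
        raise MeshError("mass and stiffness dimensions do not conform")
    A = stiffness.tocsc()
    if lumped:
        d = np.asarray(mass.sum(axis=1)).ravel()
        if np.any(d <= 0):
            raise MeshError("singular (non-positive) lumped mass matrix")
        MinvA = A.toarray() / d[:, None]
    else:
        try:
            lu = splu(mass.tocsc())
        except RuntimeError as exc:
            raise MeshError(f"singular mass matrix: {exc}") from exc
        if np.any(lu.U.diagonal() == 0):
            raise MeshError("singular mass matrix")
        MinvA = lu.solve(A.toarray())
    P = A.toarray().T @ MinvA
    return (P + P.T) / 2.0


def build_basis_system(spots: SpotSet, *, lumped_mass: bool = False) -> BasisSystem:
    """Mesh the spots and assemble all FEM matrices in one call."""
    mesh = build_mesh(spots)
    M = assemble_mass(mesh)
    A = assemble_stiffness(mesh)
    P = assemble_penalty(M, A, lumped=lumped_mass)
    logger.info(
        "basis system: %d nodes, %d triangles", mesh.n_nodes, mesh.n_triangles
    )
    return BasisSystem(mesh=mesh, mass=M, stiffness=A, penalty=P)
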