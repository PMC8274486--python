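"""Triangle-surface data model and differential-geometry primitives.

The central type is :class:`SurfaceMesh`: a connected, orientable,
manifold triangle surface with at most one boundary loop (the ostium of
a left atrial appendage), carrying named per-vertex fields, an optional
ordered boundary ring and an optional landmark vertex (the reference
closest to the circumflex artery).  On top of it sit area-weighted vertex
normals, cotangent mean / angle-defect Gaussian curvature, the cotangent
stiffness + lumped mass operator pair, and conversion to an attributed
graph with Cartesian pseudo-coordinates for spline-kernel convolutions.

All coordinates are treated as millimetres; vertex and face indices are
0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class MeshValidationError(ValueError):
    """The mesh violates a structural invariant (manifoldness, degeneracy...)."""


class UnsupportedTopologyError(ValueError):
    """The input contains non-triangular cells."""


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray  # (F, 3) int, 0-based
    fields: dict = field(default_factory=dict)
    ostium_ring: np.ndarray | None = None  # ordered boundary vertex indices
    landmark: int | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.ostium_ring is not None:
            self.ostium_ring = np.asarray(self.ostium_ring, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # ------------------------------------------------------------------
    def edges_unique(self) -> np.ndarray:
        """Undirected edges (E, 2), sorted pairs, deduplicated."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of boundary edges (edges on exactly one face)."""
        e_dir = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = np.sort(e_dir, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        boundary = e_dir[counts[inv] == 1]
        if len(boundary) == 0:
            return []
        nxt = dict(zip(boundary[:, 0].tolist(), boundary[:, 1].tolist()))
        loops = []
        remaining = set(nxt)
        while remaining:
            start = min(remaining)
            loop = [start]
            remaining.discard(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                remaining.discard(cur)
                cur = nxt[cur]
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def validate(self) -> "SurfaceMesh":
        V, F = self.n_vertices, self.faces
        if F.min(initial=0) < 0 or (len(F) and F.max() >= V):
            raise MeshValidationError("face indices out of range")
        if np.any(
            (F[:, 0] == F[:, 1]) | (F[:, 1] == F[:, 2]) | (F[:, 0] == F[:, 2])
        ):
            raise MeshValidationError("degenerate face: repeated vertex index")
        areas = self.face_areas()
        bad = np.flatnonzero(areas <= 0)
        if len(bad):
            raise MeshValidationError(f"zero-area faces: {bad.tolist()[:10]}")
        # edge-manifold: every undirected edge on at most 2 faces, and a
        # consistently oriented surface never repeats a directed edge
        e_dir = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
        key = np.sort(e_dir, axis=1)
        uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        if counts.max(initial=0) > 2:
            offenders = uniq[counts > 2]
            raise MeshValidationError(
                f"non-manifold edges (shared by >2 faces): {offenders.tolist()[:10]}"
            )
        d_uniq, d_counts = np.unique(e_dir, axis=0, return_counts=True)
        if d_counts.max(initial=0) > 1:
            raise MeshValidationError(
                "inconsistent orientation: repeated directed edge "
                f"{d_uniq[d_counts > 1].tolist()[:10]}"
            )
        eu = self.edges_unique()
        adj = sp.coo_matrix(
            (np.ones(len(eu)), (eu[:, 0], eu[:, 1])), shape=(V, V)
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp > 1:
            raise MeshValidationError(f"mesh has {n_comp} connected components")
        if len(self.boundary_loops()) > 1:
            raise MeshValidationError("more than one boundary loop")
        return self


@dataclass
class MeshGraph:
    n_nodes: int
    edges: np.ndarray  # (2E, 2) directed pairs (i, j)
    pseudo_coords: np.ndarray  # (2E, 3) in [0, 1]^3
    node_features: np.ndarray | None = None


@dataclass
class LinearOperatorPair:
    stiffness: sp.csr_matrix  # cotangent Laplacian, PSD, rows sum to 0
    mass: sp.dia_matrix  # lumped (barycentric) vertex areas


# ----------------------------------------------------------------------
def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit per-vertex normals, area-weighted average of incident faces."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, f[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    zero = np.flatnonzero(norms < 1e-300)
    if len(zero):
        raise MeshValidationError(f"zero-area vertex star at vertices {zero.tolist()[:10]}")
    return vn / norms[:, None]


def _cot_weights(mesh: SurfaceMesh):
    """Per-face corner cotangents and the (i, j, w) COO triplets of the
    cotangent stiffness matrix with w_ij = (cot a_ij + cot b_ij) / 2."""
    v, f = mesh.vertices, mesh.faces
    rows, cols, vals = [], [], []
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        a, b = v[i] - v[o], v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cot = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def build_operators(mesh: SurfaceMesh) -> LinearOperatorPair:
    """Cotangent stiffness and lumped barycentric mass matrices."""
    areas = mesh.face_areas()
    bad = np.flatnonzero(areas <= 0)
    if len(bad):
        raise MeshValidationError(f"degenerate faces: {bad.tolist()[:10]}")
    V = mesh.n_vertices
    r, c, w = _cot_weights(mesh)
    W = sp.coo_matrix((w, (r, c)), shape=(V, V)).tocsr()
    W = 0.5 * (W + W.T)  # symmetrize exactly
    d = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(d) - W
    m = np.zeros(V)
    for k in range(3):
        np.add.at(m, mesh.faces[:, k], areas / 3.0)
    return LinearOperatorPair(stiffness=L.tocsr(), mass=sp.diags(m))


def _nearest_interior_fill(mesh: SurfaceMesh, values: np.ndarray, boundary: np.ndarray):
    """Overwrite boundary vertices with the mean value of the interior
    vertices at minimal edge-graph distance (a relabel-invariant
    nearest-interior-neighbour rule)."""
    V = mesh.n_vertices
    interior = np.ones(V, bool)
    interior[boundary] = False
    eu = mesh.edges_unique()
    nbr: list[list[int]] = [[] for _ in range(V)]
    for a, b in eu:
        nbr[a].append(b)
        nbr[b].append(a)
    out = values.copy()
    for bv in boundary:
        frontier = {int(bv)}
        seen = set(frontier)
        while frontier:
            hits = [v for v in frontier if interior[v]]
            if hits:
                out[bv] = float(np.mean(values[sorted(hits)]))
                break
            frontier = {
                n for cur in frontier for n in nbr[cur] if n not in seen
            }
            seen |= frontier
    return out


def vertex_curvature(mesh: SurfaceMesh, kind: str = "mean") -> np.ndarray:
    """Per-vertex curvature.

    mean: signed cotangent mean curvature H = (L x . n) / (2 A_v)
    (positive on convex regions of an outward-oriented surface);
    gaussian: angle defect divided by the lumped vertex area.
    Open-boundary vertices inherit the value of their nearest interior
    neighbour, where the discretizations are undefined.
    """
    ops = build_operators(mesh)
    area = ops.mass.diagonal()
    if kind == "mean":
        lx = ops.stiffness @ mesh.vertices
        n = vertex_normals(mesh)
        h = np.einsum("ij,ij->i", lx, n) / (2.0 * area)
    elif kind == "gaussian":
        v, f = mesh.vertices, mesh.faces
        angle_sum = np.zeros(mesh.n_vertices)
        for k in range(3):
            o, i, j = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
            a = v[i] - v[o]
            b = v[j] - v[o]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            np.add.at(angle_sum, o, np.arccos(np.clip(cosang, -1, 1)))
        h = (2.0 * np.pi - angle_sum) / area
    else:
        raise ValueError(f"unknown curvature kind {kind!r}")
    loops = mesh.boundary_loops()
    if loops:
        h = _nearest_interior_fill(mesh, h, np.concatenate(loops))
    return h


def mesh_to_graph(mesh: SurfaceMesh, features: np.ndarray | None = None) -> MeshGraph:
    """Attributed graph with both orientations of every mesh edge and
    pseudo-coordinates u(i->j) = (p_j - p_i) / (2 s) + 1/2, where s is the
    largest per-axis coordinate difference over all edges of this mesh."""
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshValidationError("non-finite vertex positions")
    eu = mesh.edges_unique()
    edges = np.vstack([eu, eu[:, ::-1]])
    delta = mesh.vertices[edges[:, 1]] - mesh.vertices[edges[:, 0]]
    s = np.abs(delta).max()
    if s == 0:
        raise MeshValidationError("all edge vectors vanish")
    pseudo = delta / (2.0 * s) + 0.5
    if features is not None:
        features = np.asarray(features, dtype=np.float64)
        if len(features) != mesh.n_vertices:
            raise ValueError("feature rows must align with vertices")
    return MeshGraph(
        n_nodes=mesh.n_vertices,
        edges=edges,
        pseudo_coords=pseudo,
        node_features=features,
    )
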