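"""Surface flattening of the left atrial appendage.

The parameterization follows the clinical bull's-eye convention: the
geodesic distance from the ostium ring (computed with the heat method)
provides the radial coordinate, and an angular coordinate is obtained on
each distance isoline by pivoting around the isoline centroid, with the
point closest to the circumflex-artery landmark fixing the 0 degree
reference.  Sampling R isolines at A angles each yields an (R, A) grid
of surface locations whose xyz channels feed image-based surrogates;
barycentric correspondence records allow any grid field to be
transported back onto the mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .mesh import SurfaceMesh, build_operators

log = logging.getLogger(__name__)

__all__ = [
    "geodesic_distance",
    "apex_vertex",
    "extract_isolines",
    "angular_parameterize",
    "build_flat_map",
    "sample_field",
    "to_bullseye",
    "unflatten",
    "FlatMap",
    "BullsEye",
    "Isoline",
]


# ------------------------------------------------------------- heat method
def _face_grad(mesh: SurfaceMesh, u: np.ndarray) -> np.ndarray:
    """Per-face gradient of a vertex scalar."""
    v, f = mesh.vertices, mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    dbl_area = np.linalg.norm(n, axis=1)
    nu = n / dbl_area[:, None]
    # gradient of hat function at vertex i is (N x opposite_edge) / (2A)
    g = (
        u[f[:, 0], None] * np.cross(nu, p2 - p1)
        + u[f[:, 1], None] * np.cross(nu, p0 - p2)
        + u[f[:, 2], None] * np.cross(nu, p1 - p0)
    )
    return g / dbl_area[:, None]


def _divergence(mesh: SurfaceMesh, X: np.ndarray) -> np.ndarray:
    """Integrated divergence of a per-face vector field at vertices."""
    v, f = mesh.vertices, mesh.faces
    div = np.zeros(mesh.n_vertices)
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        # edges leaving vertex i within the face; cotangents at the
        # vertices opposite to those edges
        e1 = v[j] - v[i]
        e2 = v[o] - v[i]

        def cot(a, b):
            cr = np.linalg.norm(np.cross(a, b), axis=1)
            return np.einsum("ij,ij->i", a, b) / np.maximum(cr, 1e-300)

        cot1 = cot(v[i] - v[o], v[j] - v[o])  # opposite e1
        cot2 = cot(v[i] - v[j], v[o] - v[j])  # opposite e2
        contrib = 0.5 * (
            cot1 * np.einsum("ij,ij->i", e1, X) + cot2 * np.einsum("ij,ij->i", e2, X)
        )
        np.add.at(div, i, contrib)
    return div


def geodesic_distance(mesh: SurfaceMesh, source: np.ndarray) -> np.ndarray:
    """Heat-method geodesic distance from a vertex set.

    Solves (M + t L) u = delta_source with t the squared mean edge
    length, normalizes the negated gradient and integrates it back with
    a Poisson solve; the result is shifted so the minimum over the
    source set is exactly zero.
    """
    source = np.atleast_1d(np.asarray(source, dtype=np.int64))
    if len(source) == 0:
        raise ValueError("source set is empty")
    eu = mesh.edges_unique()
    adj = sp.coo_matrix(
        (np.ones(len(eu)), (eu[:, 0], eu[:, 1])), shape=(mesh.n_vertices,) * 2
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        unreachable = np.flatnonzero(labels != labels[source[0]])
        raise ValueError(f"vertices unreachable from source: {unreachable.tolist()[:10]}")

    ops = build_operators(mesh)
    L, M = ops.stiffness, ops.mass
    edge_len = np.linalg.norm(
        mesh.vertices[eu[:, 0]] - mesh.vertices[eu[:, 1]], axis=1
    )
    t = float(edge_len.mean()) ** 2

    delta = np.zeros(mesh.n_vertices)
    delta[source] = 1.0
    u = factorized((M + t * L).tocsc())(delta)

    g = _face_grad(mesh, u)
    gn = np.linalg.norm(g, axis=1)
    X = -g / np.maximum(gn, 1e-300)[:, None]
    div = _divergence(mesh, X)

    # L has a constant nullspace; a tiny mass shift pins it
    phi = factorized((L + 1e-10 * M).tocsc())(div)
    phi = phi - phi[source].min()
    # the Poisson solve may flip sign on tiny meshes; distances grow away
    # from the source by construction of X
    if phi.mean() < 0:
        phi = -phi + phi[source].min()
        phi = phi - phi[source].min()
    phi[source] = 0.0
    return np.maximum(phi, 0.0)


def apex_vertex(dist: np.ndarray) -> int:
    """Vertex of largest geodesic distance (ties -> lowest index)."""
    return int(np.argmax(dist))


# ------------------------------------------------------------- isolines
@dataclass
class Isoline:
    level: float
    points: np.ndarray  # (n, 3) crossing points in traversal order
    edges: np.ndarray  # (n, 2) mesh edge (va, vb) carrying each point
    edge_t: np.ndarray  # (n,) interpolation parameter along (va, vb)
    seg_faces: np.ndarray  # (n,) face of segment points[i] -> points[i+1]

    def length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    def reversed(self) -> "Isoline":
        n = len(self.points)
        idx = np.arange(n)[::-1]
        return Isoline(
            level=self.level,
            points=self.points[idx],
            edges=self.edges[idx],
            edge_t=self.edge_t[idx],
            seg_faces=np.roll(self.seg_faces[idx], -1),
        )


def _extract_level(mesh: SurfaceMesh, dist: np.ndarray, level: float) -> list[Isoline]:
    v, f = mesh.vertices, mesh.faces
    above = dist > level
    cross_mask = above[f].sum(axis=1) % 3 != 0  # faces with 1 or 2 vertices above
    face_ids = np.flatnonzero(cross_mask)
    if len(face_ids) == 0:
        raise ValueError(f"isoline level {level} has no crossings")

    # crossing points keyed by undirected mesh edge
    edge_pt: dict[tuple[int, int], tuple[np.ndarray, float, int, int]] = {}
    face_edges: dict[int, list[tuple[int, int]]] = {}
    for fi in face_ids:
        tri = f[fi]
        crossed = []
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            if above[a] != above[b]:
                key = (a, b) if a < b else (b, a)
                crossed.append(key)
                if key not in edge_pt:
                    va, vb = key
                    t = (level - dist[va]) / (dist[vb] - dist[va])
                    edge_pt[key] = (v[va] * (1 - t) + v[vb] * t, t, va, vb)
        face_edges[int(fi)] = crossed

    # adjacency: each crossed edge belongs to <= 2 crossing faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, keys in face_edges.items():
        for key in keys:
            edge_faces.setdefault(key, []).append(fi)

    loops: list[Isoline] = []
    unused = set(face_edges)
    while unused:
        f0 = unused.pop()
        keys = face_edges[f0]
        if len(keys) != 2:
            continue  # boundary-touching chain; skipped (open isolines)
        point_keys = [keys[0]]
        seg_faces = [f0]
        cur_key, cur_face = keys[1], f0
        closed = True
        while True:
            nbrs = [x for x in edge_faces[cur_key] if x != cur_face]
            if not nbrs:
                closed = False
                break
            nxt = nbrs[0]
            if nxt not in unused:
                break
            unused.discard(nxt)
            point_keys.append(cur_key)
            seg_faces.append(nxt)
            k2 = [x for x in face_edges[nxt] if x != cur_key]
            cur_key, cur_face = k2[0], nxt
        if not closed or len(point_keys) < 3:
            continue
        pts = np.array([edge_pt[k][0] for k in point_keys])
        edges = np.array([[edge_pt[k][2], edge_pt[k][3]] for k in point_keys])
        ts = np.array([edge_pt[k][1] for k in point_keys])
        loops.append(
            Isoline(
                level=level,
                points=pts,
                edges=edges,
                edge_t=ts,
                seg_faces=np.array(seg_faces, dtype=np.int64),
            )
        )
    if not loops:
        raise ValueError(f"no closed isoline at level {level}")
    return loops


def extract_isolines(mesh: SurfaceMesh, dist: np.ndarray, R: int) -> list[Isoline]:
    """R closed isolines at the epsilon-inset levels (r + 1/2)/R * d_max.

    Where a level splits into several loops (lobed anatomies) the longest
    loop is kept and the event logged.
    """
    if R < 2:
        raise ValueError("need at least two isolines")
    d_max = float(dist.max())
    if d_max <= 0:
        raise ValueError("distance field is constant")
    levels = (np.arange(R) + 0.5) / R * d_max
    out = []
    for lv in levels:
        loops = _extract_level(mesh, dist, lv)
        if len(loops) > 1:
            log.info(
                "isoline level %.4g split into %d loops; keeping the longest",
                lv,
                len(loops),
            )
            loops.sort(key=lambda p: p.length(), reverse=True)
        out.append(loops[0])
    return out


# ------------------------------------------------------- angular mapping
def _plane_basis(axis: np.ndarray):
    axis = axis / np.linalg.norm(axis)
    h = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(h, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def angular_parameterize(
    points: np.ndarray, landmark_pos: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Angles in [0, 2pi) about the loop centroid, counter-clockwise
    around `axis`, with the point nearest `landmark_pos` at angle 0.

    The loop must traverse counter-clockwise about the axis; mild
    non-monotonicity (lobed projections) is repaired monotonically and
    logged.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        raise ValueError("need at least three points")
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis must be nonzero")
    c = points.mean(axis=0)
    e1, e2 = _plane_basis(np.asarray(axis, dtype=np.float64))
    d = points - c
    x, y = d @ e1, d @ e2
    r = np.hypot(x, y)
    if np.any(r < 1e-12):
        raise ValueError("point coincides with the loop centroid after projection")
    raw = np.arctan2(y, x)
    i0 = int(np.argmin(np.linalg.norm(points - landmark_pos, axis=1)))
    ang = np.mod(raw - raw[i0], 2.0 * np.pi)
    # repair mild non-monotonicity along the traversal starting at i0
    order = np.roll(np.arange(len(points)), -i0)
    a = ang[order]
    if np.any(np.diff(a) <= 0):
        log.info("non-monotone angular traversal repaired monotonically")
        a = np.maximum.accumulate(a)
        flat = np.flatnonzero(np.diff(a) <= 0)
        a[flat + 1] = np.nextafter(a[flat], np.inf) + 1e-12
        a = np.minimum(a, np.nextafter(2.0 * np.pi, 0.0))
        ang[order] = a
    return ang


# ------------------------------------------------------------- flat map
@dataclass
class FlatMap:
    grid_shape: tuple[int, int]
    channels: np.ndarray  # (R, A, 3) sampled xyz
    corr_faces: np.ndarray  # (R, A) face indices
    corr_bary: np.ndarray  # (R, A, 3) barycentric weights
    d_levels: np.ndarray  # (R,) normalized geodesic levels in (0, 1)
    theta: np.ndarray  # (A,) angles in [0, 2pi)
    d_max: float
    row_centroids: np.ndarray  # (R, 3)
    row_axes: np.ndarray  # (R, 3)
    row_refs: np.ndarray  # (R, 3) direction of angle 0 in each row plane
    vertex_dist_norm: np.ndarray  # (V,) normalized geodesic depth per vertex

    def save_npz(self, path: str):
        np.savez(
            path,
            channels=self.channels,
            correspondence_faces=self.corr_faces,
            correspondence_bary=self.corr_bary,
            d_levels=self.d_levels,
            theta=self.theta,
            d_max=self.d_max,
            row_centroids=self.row_centroids,
            row_axes=self.row_axes,
            row_refs=self.row_refs,
            vertex_dist_norm=self.vertex_dist_norm,
        )

    @classmethod
    def load_npz(cls, path: str) -> "FlatMap":
        with np.load(path) as z:
            ch = z["channels"]
            return cls(
                grid_shape=ch.shape[:2],
                channels=ch,
                corr_faces=z["correspondence_faces"],
                corr_bary=z["correspondence_bary"],
                d_levels=z["d_levels"],
                theta=z["theta"],
                d_max=float(z["d_max"]),
                row_centroids=z["row_centroids"],
                row_axes=z["row_axes"],
                row_refs=z["row_refs"],
                vertex_dist_norm=z["vertex_dist_norm"],
            )


@dataclass
class BullsEye:
    image: np.ndarray  # (S, S, C)
    mask: np.ndarray  # (S, S) bool, True inside the unit disc
    pad_value: float


def _barycentric(mesh: SurfaceMesh, face: int, point: np.ndarray) -> np.ndarray:
    tri = mesh.vertices[mesh.faces[face]]
    T = np.column_stack([tri[1] - tri[0], tri[2] - tri[0]])
    rhs = point - tri[0]
    sol, *_ = np.linalg.lstsq(T, rhs, rcond=None)
    b = np.array([1.0 - sol[0] - sol[1], sol[0], sol[1]])
    b = np.clip(b, 0.0, None)
    return b / b.sum()


def build_flat_map(
    mesh: SurfaceMesh,
    dist: np.ndarray,
    landmark: int,
    R: int = 128,
    A: int = 128,
) -> FlatMap:
    """Sample R isolines at A angles each into an (R, A) grid.

    Row order is increasing geodesic distance from the ostium; the
    per-row axis is the mean geodesic-gradient direction across the
    loop, sign-fixed toward the apex.
    """
    if R < 2 or A < 4:
        raise ValueError("require R >= 2 and A >= 4")
    if not 0 <= landmark < mesh.n_vertices:
        raise ValueError("invalid landmark vertex")
    d_max = float(dist.max())
    apex_pos = mesh.vertices[apex_vertex(dist)]
    landmark_pos = mesh.vertices[landmark]
    grad = _face_grad(mesh, dist)
    isolines = extract_isolines(mesh, dist, R)

    theta = 2.0 * np.pi * np.arange(A) / A
    channels = np.zeros((R, A, 3))
    corr_faces = np.zeros((R, A), dtype=np.int64)
    corr_bary = np.zeros((R, A, 3))
    centroids = np.zeros((R, 3))
    axes = np.zeros((R, 3))
    refs = np.zeros((R, 3))

    for r, iso in enumerate(isolines):
        g = grad[iso.seg_faces]
        axis = g.mean(axis=0)
        nrm = np.linalg.norm(axis)
        axis = g[0] if nrm < 1e-12 else axis / nrm
        c = iso.points.mean(axis=0)
        if np.dot(axis, apex_pos - c) < 0:
            axis = -axis
        # orient the loop counter-clockwise about the axis
        e1, e2 = _plane_basis(axis)
        d2 = iso.points - c
        x, y = d2 @ e1, d2 @ e2
        winding = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if winding < 0:
            iso = iso.reversed()
        ang = angular_parameterize(iso.points, landmark_pos, axis)
        i0 = int(np.argmin(np.linalg.norm(iso.points - landmark_pos, axis=1)))
        ref_vec = iso.points[i0] - c
        ref_vec -= axis * np.dot(ref_vec, axis)
        refs[r] = ref_vec / np.linalg.norm(ref_vec)
        centroids[r], axes[r] = c, axis

        order = np.roll(np.arange(len(iso.points)), -i0)
        a_sorted = ang[order]
        pts = iso.points[order]
        segf = iso.seg_faces[order]  # face of segment order[i] -> order[i+1]
        # wrap-around closure
        a_ext = np.concatenate([a_sorted, [a_sorted[0] + 2.0 * np.pi]])
        idx = np.searchsorted(a_ext, theta, side="right") - 1
        idx = np.clip(idx, 0, len(pts) - 1)
        nxt = (idx + 1) % len(pts)
        span = a_ext[idx + 1] - a_ext[idx]
        s = np.where(span > 0, (theta - a_ext[idx]) / np.where(span > 0, span, 1.0), 0.0)
        sampled = pts[idx] * (1 - s)[:, None] + pts[nxt] * s[:, None]
        channels[r] = sampled
        for a_i in range(A):
            fidx = int(segf[idx[a_i]])
            corr_faces[r, a_i] = fidx
            corr_bary[r, a_i] = _barycentric(mesh, fidx, sampled[a_i])

    return FlatMap(
        grid_shape=(R, A),
        channels=channels,
        corr_faces=corr_faces,
        corr_bary=corr_bary,
        d_levels=np.array([iso.level for iso in isolines]) / d_max,
        theta=theta,
        d_max=d_max,
        row_centroids=centroids,
        row_axes=axes,
        row_refs=refs,
        vertex_dist_norm=dist / d_max,
    )


def sample_field(field: np.ndarray, mesh: SurfaceMesh, flat: FlatMap) -> np.ndarray:
    """Sample a per-vertex scalar field onto the (R, A) grid via the
    stored barycentric correspondence."""
    tri = mesh.faces[flat.corr_faces]  # (R, A, 3)
    return np.einsum("rac,rac->ra", field[tri], flat.corr_bary)


def to_bullseye(
    flat: FlatMap, S: int, values: np.ndarray, pad_value: float = 0.0
) -> BullsEye:
    """Rasterize (R, A, C) grid channels to an S x S polar image with the
    apex at the centre (rho = 1 - depth) and the ostium at the rim."""
    if S < 16:
        raise ValueError("raster size must be >= 16")
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 2:
        values = values[:, :, None]
    R, A, C = values.shape
    ys, xs = np.mgrid[0:S, 0:S]
    cx = (S - 1) / 2.0
    u = (xs - cx) / (S / 2.0)
    v = (ys - cx) / (S / 2.0)
    rho = np.hypot(u, v)
    th = np.mod(np.arctan2(v, u), 2.0 * np.pi)
    mask = rho <= 1.0

    depth = 1.0 - rho  # apex (centre) = depth 1
    img = np.full((S, S, C), float(pad_value))
    d = np.clip(depth, flat.d_levels[0], flat.d_levels[-1])
    r_f = np.interp(d, flat.d_levels, np.arange(R))
    r0 = np.clip(np.floor(r_f).astype(int), 0, R - 1)
    r1 = np.minimum(r0 + 1, R - 1)
    wr = r_f - r0
    a_f = th / (2.0 * np.pi) * A
    a0 = np.floor(a_f).astype(int) % A
    a1 = (a0 + 1) % A
    wa = a_f - np.floor(a_f)
    interp = (
        values[r0, a0] * ((1 - wr) * (1 - wa))[..., None]
        + values[r1, a0] * (wr * (1 - wa))[..., None]
        + values[r0, a1] * ((1 - wr) * wa)[..., None]
        + values[r1, a1] * (wr * wa)[..., None]
    )
    img[mask] = interp[mask]
    return BullsEye(image=img, mask=mask, pad_value=float(pad_value))


def _row_angle(flat: FlatMap, r: int, points: np.ndarray) -> np.ndarray:
    axis, c, ref = flat.row_axes[r], flat.row_centroids[r], flat.row_refs[r]
    d = points - c
    e2 = np.cross(axis, ref)
    return np.mod(np.arctan2(d @ e2, d @ ref), 2.0 * np.pi)


def _interp_row(flat: FlatMap, grid_row: np.ndarray, ang: np.ndarray) -> np.ndarray:
    A = len(flat.theta)
    a_f = ang / (2.0 * np.pi) * A
    a0 = np.floor(a_f).astype(int) % A
    a1 = (a0 + 1) % A
    w = a_f - np.floor(a_f)
    return grid_row[a0] * (1 - w) + grid_row[a1] * w


def unflatten(mesh: SurfaceMesh, flat: FlatMap, grid_values: np.ndarray) -> np.ndarray:
    """Transport an (R, A) grid field back to per-vertex values by
    bilinear interpolation in (normalized depth, angle); vertices outside
    the sampled depth range clamp to the nearest row."""
    grid_values = np.asarray(grid_values, dtype=np.float64)
    R, A = flat.grid_shape
    if grid_values.shape != (R, A):
        raise ValueError("grid shape mismatch")
    d = np.clip(flat.vertex_dist_norm, flat.d_levels[0], flat.d_levels[-1])
    r_f = np.interp(d, flat.d_levels, np.arange(R))
    r0 = np.clip(np.floor(r_f).astype(int), 0, R - 1)
    r1 = np.minimum(r0 + 1, R - 1)
    wr = r_f - r0
    out = np.zeros(mesh.n_vertices)
    for r in np.unique(np.concatenate([r0, r1])):
        sel0 = r0 == r
        if np.any(sel0):
            ang = _row_angle(flat, r, mesh.vertices[sel0])
            out[sel0] += (1 - wr[sel0]) * _interp_row(flat, grid_values[r], ang)
        sel1 = r1 == r
        if np.any(sel1):
            ang = _row_angle(flat, r, mesh.vertices[sel1])
            out[sel1] += wr[sel1] * _interp_row(flat, grid_values[r], ang)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite values after back-transport")
    return out


def bullseye_png(be: BullsEye, path: str, channel: int = 0):
    """8-bit grayscale PNG preview of one bull's-eye channel."""
    from PIL import Image

    img = be.image[:, :, channel]
    lo, hi = img[be.mask].min(), img[be.mask].max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    arr = np.zeros_like(img)
    arr[be.mask] = (img[be.mask] - lo) * scale
    Image.fromarray(arr.astype(np.uint8)).save(path)
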