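"""Mesh input/output.

VTK legacy (``.vtk``) and VTK XML PolyData (``.vtp``) are read and
written natively in ASCII, carrying named per-vertex point-data arrays.
PLY/STL/OBJ go through trimesh; for those formats per-vertex fields live
in a sidecar ``<stem>.fields.npz`` keyed by field name.  STL input is
vertex-welded on exact coordinate match to recover shared topology.

The ostium ring and the landmark travel as integer point-data arrays:
``ostium_ring_order`` (-1 off the ring, else the position along the
ring) and ``landmark`` (1 at the landmark vertex, 0 elsewhere).
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np
import trimesh

from .mesh import SurfaceMesh, UnsupportedTopologyError

_TRIMESH_FORMATS = {"ply", "stl", "obj"}


def _encode_markers(mesh: SurfaceMesh) -> dict[str, np.ndarray]:
    arrays = dict(mesh.fields)
    if mesh.ostium_ring is not None:
        order = -np.ones(mesh.n_vertices, dtype=np.int64)
        order[mesh.ostium_ring] = np.arange(len(mesh.ostium_ring))
        arrays["ostium_ring_order"] = order
    if mesh.landmark is not None:
        lm = np.zeros(mesh.n_vertices, dtype=np.int64)
        lm[mesh.landmark] = 1
        arrays["landmark"] = lm
    return arrays


def _decode_markers(arrays: dict[str, np.ndarray]):
    fields = dict(arrays)
    ring = landmark = None
    order = fields.pop("ostium_ring_order", None)
    if order is not None:
        on = np.flatnonzero(order >= 0)
        ring = on[np.argsort(order[on])]
    lm = fields.pop("landmark", None)
    if lm is not None and np.any(lm > 0):
        landmark = int(np.flatnonzero(lm > 0)[0])
    return fields, ring, landmark


# ---------------------------------------------------------------- VTK legacy
def _write_vtk(mesh: SurfaceMesh, path: str):
    arrays = _encode_markers(mesh)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlaaecap surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if arrays:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in arrays.items():
                arr = np.asarray(arr)
                comps = 1 if arr.ndim == 1 else arr.shape[1]
                dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                fh.write(f"SCALARS {name} {dtype} {comps}\n")
                fh.write("LOOKUP_TABLE default\n")
                flat = arr.reshape(mesh.n_vertices, -1)
                for row in flat:
                    fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def _read_vtk(path: str) -> SurfaceMesh:
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    it = iter(tokens_lines)
    verts = faces = None
    arrays: dict[str, np.ndarray] = {}
    n_points = 0
    line = next(it, None)
    while line is not None:
        t = line.split()
        if not t:
            line = next(it, None)
            continue
        kw = t[0].upper()
        if kw == "POINTS":
            n_points = int(t[1])
            vals: list[float] = []
            while len(vals) < 3 * n_points:
                vals += [float(x) for x in next(it).split()]
            verts = np.array(vals).reshape(n_points, 3)
        elif kw in ("POLYGONS", "TRIANGLE_STRIPS"):
            if kw == "TRIANGLE_STRIPS":
                raise UnsupportedTopologyError("triangle strips are not supported")
            n_poly, n_ints = int(t[1]), int(t[2])
            vals = []
            while len(vals) < n_ints:
                vals += [int(x) for x in next(it).split()]
            faces_list = []
            i = 0
            while i < n_ints:
                k = vals[i]
                if k != 3:
                    raise UnsupportedTopologyError(
                        f"non-triangular cell with {k} vertices"
                    )
                faces_list.append(vals[i + 1 : i + 4])
                i += k + 1
            faces = np.array(faces_list, dtype=np.int64)
        elif kw == "SCALARS":
            name, comps = t[1], int(t[3]) if len(t) > 3 else 1
            is_int = t[2].lower() in ("int", "long", "short")
            nxt = next(it)  # LOOKUP_TABLE line
            if not nxt.upper().startswith("LOOKUP_TABLE"):
                raise IOError("malformed SCALARS block")
            vals = []
            while len(vals) < n_points * comps:
                vals += [float(x) for x in next(it).split()]
            arr = np.array(vals).reshape(n_points, comps)
            if comps == 1:
                arr = arr.ravel()
            arrays[name] = arr.astype(np.int64) if is_int else arr
        line = next(it, None)
    if verts is None or faces is None:
        raise IOError(f"{path}: no polydata found")
    fields, ring, lm = _decode_markers(arrays)
    return SurfaceMesh(verts, faces, fields=fields, ostium_ring=ring, landmark=lm)


# ---------------------------------------------------------------- VTP (XML)
def _write_vtp(mesh: SurfaceMesh, path: str):
    arrays = _encode_markers(mesh)

    def da(name, arr, comps):
        flat = np.asarray(arr).reshape(-1)
        dtype = "Int64" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "Float64"
        body = " ".join(
            str(int(x)) if dtype == "Int64" else f"{x:.17g}" for x in flat
        )
        return (
            f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{comps}" format="ascii">{body}</DataArray>'
        )

    pd = "".join(
        da(name, arr, 1 if np.asarray(arr).ndim == 1 else np.asarray(arr).shape[1])
        for name, arr in arrays.items()
    )
    conn = " ".join(str(i) for i in mesh.faces.reshape(-1))
    offs = " ".join(str(3 * (i + 1)) for i in range(mesh.n_faces))
    with open(path, "w") as fh:
        fh.write(
            '<?xml version="1.0"?>\n'
            '<VTKFile type="PolyData" version="1.0" byte_order="LittleEndian">'
            f'<PolyData><Piece NumberOfPoints="{mesh.n_vertices}" '
            f'NumberOfPolys="{mesh.n_faces}">'
            f"<PointData>{pd}</PointData>"
            "<Points>"
            + da("Points", mesh.vertices, 3)
            + "</Points><Polys>"
            f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>'
            f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>'
            "</Polys></Piece></PolyData></VTKFile>"
        )


def _read_vtp(path: str) -> SurfaceMesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise IOError(f"{path}: no <Piece> element")

    def parse_da(el):
        txt = (el.text or "").split()
        if el.get("type", "").startswith("Int"):
            arr = np.array([int(x) for x in txt], dtype=np.int64)
        else:
            arr = np.array([float(x) for x in txt])
        comps = int(el.get("NumberOfComponents", "1"))
        return arr.reshape(-1, comps) if comps > 1 else arr

    pts_el = piece.find("./Points/DataArray")
    verts = parse_da(pts_el)
    polys = {el.get("Name"): parse_da(el) for el in piece.findall("./Polys/DataArray")}
    conn, offs = polys["connectivity"], polys["offsets"]
    sizes = np.diff(np.concatenate([[0], offs]))
    if np.any(sizes != 3):
        raise UnsupportedTopologyError(
            f"non-triangular cell with {int(sizes[sizes != 3][0])} vertices"
        )
    faces = conn.reshape(-1, 3)
    arrays = {
        el.get("Name"): parse_da(el)
        for el in piece.findall("./PointData/DataArray")
    }
    fields, ring, lm = _decode_markers(arrays)
    return SurfaceMesh(verts, faces, fields=fields, ostium_ring=ring, landmark=lm)


# ---------------------------------------------------------------- public API
def detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in {"vtk", "vtp"} | _TRIMESH_FORMATS:
        return ext
    raise IOError(f"cannot infer mesh format from {path!r}")


def read_mesh(path: str, format: str = "auto") -> SurfaceMesh:
    """Read a triangle surface; validates structural invariants."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = detect_format(path) if format == "auto" else format
    if fmt == "vtk":
        mesh = _read_vtk(path)
    elif fmt == "vtp":
        mesh = _read_vtp(path)
    elif fmt in _TRIMESH_FORMATS:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
        verts = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(tm.faces, dtype=np.int64)
        if fmt == "stl":
            # exact-coordinate weld to recover shared topology
            uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
            verts, faces = uniq, inverse[faces]
        mesh = SurfaceMesh(verts, faces)
        sidecar = os.path.splitext(path)[0] + ".fields.npz"
        if os.path.exists(sidecar):
            with np.load(sidecar) as npz:
                fields, ring, lm = _decode_markers({k: npz[k] for k in npz.files})
            mesh.fields.update(fields)
            mesh.ostium_ring, mesh.landmark = ring, lm
    else:
        raise IOError(f"unknown format {fmt!r}")
    return mesh.validate()


def write_mesh(mesh: SurfaceMesh, path: str, format: str = "auto"):
    fmt = detect_format(path) if format == "auto" else format
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "vtp":
        _write_vtp(mesh, path)
    elif fmt in _TRIMESH_FORMATS:
        tm = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces, process=False
        )
        tm.export(path, file_type=fmt)
        arrays = _encode_markers(mesh)
        if arrays:
            np.savez(os.path.splitext(path)[0] + ".fields.npz", **arrays)
    else:
        raise IOError(f"unknown format {fmt!r}")
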