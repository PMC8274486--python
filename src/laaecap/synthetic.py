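"""Synthetic left-atrial-appendage anatomies with a closed-form
hemodynamic oracle.

Clinical LAA meshes and the CFD fields computed on them are not
publicly deposited, so experiments here run on a parametric stand-in:
a lobed, bent, tapering tube sharing one template topology across all
samples (correspondence by construction, so the PCA shape model applies
directly), with an open ostium ring, an apex cap and a fixed landmark
vertex on the ring playing the circumflex-artery reference.

The oracle maps geometry to (TAWSS*, OSI*, ECAP*): oscillatory shear
grows with normalized geodesic depth from the ostium and inside lobes
(emulating blood stasis in appendage recesses), shear magnitude decays
with depth, and ECAP* = OSI*/TAWSS* is positively skewed across a
population, echoing the structure of CFD-derived maps.  A two-phase
reversing wall-shear series is constructed per vertex so that the index
pipeline recovers the oracle exactly under the step quadrature, making
the whole chain testable without a CFD solver.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .flatten import geodesic_distance
from .hemo import HemoFields, WSSTimeSeries
from .mesh import SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "ShapeSpec",
    "OracleSpec",
    "sample_shape",
    "oracle_fields",
    "synth_wss",
    "Case",
    "DatasetBundle",
    "make_dataset",
    "COHORTS",
]


@dataclass
class ShapeSpec:
    n_axial: int = 16  # rings along the tube axis
    n_circ: int = 12  # vertices per ring
    base_length: float = 28.0  # mm, ostium-to-apex
    base_radius: float = 9.0  # mm, ostium radius scale
    bend_amplitude: float = 6.0  # mm, quadratic centerline bend per axis
    radius_variation: float = 0.18  # relative low-order radius modulation
    lobe_count_range: tuple[int, int] = (1, 3)
    lobe_amp_range: tuple[float, float] = (2.0, 5.0)  # mm outward bulge
    lobe_width_axial: tuple[float, float] = (0.08, 0.18)  # in t units
    lobe_width_angular: tuple[float, float] = (0.45, 0.9)  # radians
    scale_range: tuple[float, float] = (0.85, 1.15)
    min_radius: float = 1.0  # mm, resample below this

    @property
    def n_vertices(self) -> int:
        return self.n_axial * self.n_circ + 1


@dataclass
class OracleSpec:
    c0: float = 0.15  # Pa, TAWSS floor at the apex
    gamma: float = 2.0  # depth exponent of oscillatory shear
    c2: float = 1.5  # lobe gain on oscillatory shear
    osi_max: float = 0.45  # peak OSI, must be <= 0.5
    osi_floor: float = 0.01  # keeps OSI strictly positive on the ring
    tawss_base: float = 1.2  # Pa at the ostium
    depth_decay: float = 0.9  # fractional TAWSS drop toward the apex
    noise_sd: float = 0.0  # smooth multiplicative field noise
    seed: int = 0


COHORTS = {
    # lobe-heavy "cauliflower"-like population -> higher ECAP in lobes
    "synthetic-like": dict(lobe_count_range=(1, 3), lobe_amp_range=(2.5, 5.0)),
    # milder anatomy with few, small lobes
    "real-like": dict(lobe_count_range=(0, 1), lobe_amp_range=(0.5, 2.0)),
}


def _template_faces(spec: ShapeSpec) -> np.ndarray:
    na, nc = spec.n_axial, spec.n_circ
    faces = []
    for j in range(na - 1):
        for i in range(nc):
            a = j * nc + i
            b = j * nc + (i + 1) % nc
            c = (j + 1) * nc + i
            d = (j + 1) * nc + (i + 1) % nc
            faces.append([a, b, d])
            faces.append([a, d, c])
    apex = na * nc
    top = (na - 1) * nc
    for i in range(nc):
        faces.append([top + i, top + (i + 1) % nc, apex])
    return np.array(faces, dtype=np.int64)


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    return np.mod(x + np.pi, 2.0 * np.pi) - np.pi


def sample_shape(spec: ShapeSpec, seed: int) -> SurfaceMesh:
    """One corresponded LAA-like mesh, deterministic per seed.

    Vertex fields carry the intrinsic coordinates (`axial_t`, `phi`) and
    the amplitude-free lobe indicator used by the oracle.  Resamples the
    deformation up to 10 times if radii collapse below `min_radius`.
    """
    faces = _template_faces(spec)
    na, nc = spec.n_axial, spec.n_circ
    t = np.arange(na) / na  # rings in [0, (na-1)/na]; apex cap at t = 1
    phi = 2.0 * np.pi * np.arange(nc) / nc

    for attempt in range(10):
        rng = np.random.default_rng([seed, attempt])
        bend = rng.uniform(-spec.bend_amplitude, spec.bend_amplitude, size=2)
        cmod = rng.uniform(-spec.radius_variation, spec.radius_variation, size=3)
        G = rng.integers(spec.lobe_count_range[0], spec.lobe_count_range[1] + 1)
        lobes = [
            dict(
                t=rng.uniform(0.3, 0.85),
                phi=rng.uniform(0, 2 * np.pi),
                amp=rng.uniform(*spec.lobe_amp_range),
                st=rng.uniform(*spec.lobe_width_axial),
                sp=rng.uniform(*spec.lobe_width_angular),
            )
            for _ in range(G)
        ]
        scale = rng.uniform(*spec.scale_range)

        T, P = np.meshgrid(t, phi, indexing="ij")  # (na, nc)
        prof = 1.0 + sum(
            cmod[m - 1] * np.sin(m * np.pi * T) for m in range(1, 4)
        )
        taper = np.cos(0.5 * np.pi * T) ** 0.8
        rho = spec.base_radius * prof * taper
        indicator = np.zeros_like(T)
        for lb in lobes:
            k = np.exp(
                -((T - lb["t"]) ** 2) / (2 * lb["st"] ** 2)
                - (_wrap_angle(P - lb["phi"]) ** 2) / (2 * lb["sp"] ** 2)
            )
            rho = rho + lb["amp"] * k
            indicator = indicator + k
        if rho.min() < spec.min_radius:
            log.info("seed %d attempt %d: radius collapse, resampling", seed, attempt)
            continue

        cx = bend[0] * T**2
        cy = bend[1] * T**2
        cz = spec.base_length * T
        verts = np.empty((na * nc + 1, 3))
        verts[: na * nc, 0] = (cx + rho * np.cos(P)).ravel()
        verts[: na * nc, 1] = (cy + rho * np.sin(P)).ravel()
        verts[: na * nc, 2] = cz.ravel()
        apex_ind = float(
            sum(np.exp(-((1.0 - lb["t"]) ** 2) / (2 * lb["st"] ** 2)) for lb in lobes)
        )
        verts[na * nc] = [bend[0], bend[1], spec.base_length]
        verts *= scale

        fields = {
            "axial_t": np.concatenate([T.ravel(), [1.0]]),
            "phi": np.concatenate([P.ravel(), [0.0]]),
            "lobe_indicator": np.concatenate([indicator.ravel(), [apex_ind]]),
        }
        mesh = SurfaceMesh(
            verts,
            faces,
            fields=fields,
            ostium_ring=np.arange(nc, dtype=np.int64),
            landmark=0,
        )
        try:
            return mesh.validate()
        except Exception:  # degenerate sample; try again
            log.info("seed %d attempt %d: invalid mesh, resampling", seed, attempt)
    raise RuntimeError(f"could not sample a valid shape for seed {seed}")


def _smooth_noise(mesh: SurfaceMesh, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.ones(mesh.n_vertices)
    t = mesh.fields["axial_t"]
    p = mesh.fields["phi"]
    coef = rng.normal(size=4)
    f = (
        coef[0] * np.sin(np.pi * t)
        + coef[1] * np.cos(2 * np.pi * t)
        + coef[2] * np.sin(p)
        + coef[3] * np.cos(p)
    ) / 2.0
    return 1.0 + sd * f


def oracle_fields(
    mesh: SurfaceMesh, spec: OracleSpec, dist: np.ndarray | None = None
) -> HemoFields:
    """Closed-form (TAWSS*, OSI*, ECAP*) from geodesic depth and lobes.

    With depth d = dist/d_max and lobe indicator b:
        OSI*   = osi_max * clip(floor + d^gamma (1 + c2 b), 0, 1)
        TAWSS* = tawss_base (1 - depth_decay * d) + c0
        ECAP*  = OSI* / TAWSS*
    so ECAP* strictly increases with depth in the absence of lobes and
    noise, and lobes raise it further.
    """
    if dist is None:
        if mesh.ostium_ring is None:
            raise ValueError("mesh has no ostium ring")
        dist = geodesic_distance(mesh, mesh.ostium_ring)
    d = dist / dist.max()
    b = mesh.fields.get("lobe_indicator", np.zeros(mesh.n_vertices))
    rng = np.random.default_rng(spec.seed)
    noise = _smooth_noise(mesh, spec.noise_sd, rng)
    osi = spec.osi_max * np.clip(
        spec.osi_floor + d**spec.gamma * (1.0 + spec.c2 * b), 0.0, 1.0
    )
    osi = np.clip(osi * noise, 1e-6, 0.5)
    tawss = (spec.tawss_base * (1.0 - spec.depth_decay * d) + spec.c0) * noise
    tawss = np.maximum(tawss, 1e-6)
    return HemoFields(tawss=tawss, osi=osi, ecap=osi / tawss)


def synth_wss(
    mesh: SurfaceMesh,
    targets: HemoFields,
    period: float = 1.0,
    n_samples_per_phase: int = 5,
) -> WSSTimeSeries:
    """Two-phase reversing step series whose indices recover `targets`
    exactly under the step quadrature.

    Solving  (a + b)/2 = TAWSS*  and  (a - b)/2 = TAWSS*(1 - 2 OSI*)
    gives a = 2 TAWSS* (1 - OSI*), b = 2 TAWSS* OSI* >= 0; the series
    holds +a e for the first half cycle and -b e for the second.
    """
    if np.any(targets.osi > 0.5):
        raise ValueError("OSI targets must not exceed 0.5")
    if np.any(targets.tawss <= 0):
        raise ValueError("TAWSS targets must be positive")
    V = mesh.n_vertices
    a = 2.0 * targets.tawss * (1.0 - targets.osi)
    b = 2.0 * targets.tawss * targets.osi
    e = np.array([1.0, 0.0, 0.0])
    K = n_samples_per_phase
    times = np.arange(2 * K) * (period / (2 * K))
    values = np.zeros((2 * K, V, 3))
    values[:K] = a[None, :, None] * e[None, None, :]
    values[K:] = -b[None, :, None] * e[None, None, :]
    return WSSTimeSeries(times=times, values=values, period=period)


# ------------------------------------------------------------- datasets
@dataclass
class Case:
    case_id: str
    mesh: SurfaceMesh
    dist: np.ndarray  # geodesic distance from the ostium
    hemo: HemoFields
    cohort: str = "synthetic-like"

    @property
    def ecap(self) -> np.ndarray:
        return self.hemo.ecap


@dataclass
class DatasetBundle:
    cases: list[Case]
    shape_spec: ShapeSpec
    oracle_spec: OracleSpec
    seed: int

    def __len__(self):
        return len(self.cases)

    def shape_stack(self) -> np.ndarray:
        return np.stack([c.mesh.vertices.reshape(-1) for c in self.cases])

    def manifest(self) -> dict:
        return {
            "n_cases": len(self.cases),
            "seed": self.seed,
            "case_ids": [c.case_id for c in self.cases],
            "cohorts": [c.cohort for c in self.cases],
            "shape_spec": asdict(self.shape_spec),
            "oracle_spec": asdict(self.oracle_spec),
        }

    def save(self, outdir: str):
        from .io import write_mesh

        os.makedirs(outdir, exist_ok=True)
        for c in self.cases:
            m = c.mesh
            m.fields.update(
                {"TAWSS": c.hemo.tawss, "OSI": c.hemo.osi, "ECAP": c.hemo.ecap,
                 "geodesic_depth": c.dist}
            )
            write_mesh(m, os.path.join(outdir, f"{c.case_id}.vtp"))
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def make_dataset(
    n: int,
    shape_spec: ShapeSpec | None = None,
    oracle_spec: OracleSpec | None = None,
    seed: int = 0,
    cohort: str = "synthetic-like",
) -> DatasetBundle:
    """n seeded corresponded cases with oracle targets attached."""
    if n < 2:
        raise ValueError("need n >= 2 cases")
    if shape_spec is None:
        shape_spec = ShapeSpec(**COHORTS.get(cohort, {}))
    oracle_spec = oracle_spec or OracleSpec()
    cases = []
    for i in range(n):
        mesh = sample_shape(shape_spec, seed=int(np.random.default_rng([seed, i]).integers(2**31)))
        dist = geodesic_distance(mesh, mesh.ostium_ring)
        hemo = oracle_fields(mesh, oracle_spec, dist)
        cases.append(
            Case(case_id=f"{cohort}-{i:04d}", mesh=mesh, dist=dist, hemo=hemo, cohort=cohort)
        )
    return DatasetBundle(cases=cases, shape_spec=shape_spec, oracle_spec=oracle_spec, seed=seed)
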