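"""Wall-shear-stress indices: TAWSS, OSI and ECAP.

Given the WSS vector tau(t) sampled per vertex over one cardiac cycle of
period T, the indices are

    TAWSS = (1/T) int |tau| dt                       [Pa]
    OSI   = 0.5 (1 - |int tau dt| / int |tau| dt)    in [0, 0.5]
    ECAP  = OSI / TAWSS                              [1/Pa]

High ECAP marks wall regions exposed to low, strongly oscillating shear
-- the hemodynamic signature of blood stasis linked to thrombus
formation in the left atrial appendage.

Quadrature is the piecewise-constant left-sample rule (exact for step
series such as CFD exports at a fixed write interval); a trapezoidal
option is available.  Where the series is identically zero, OSI is 0 by
convention (no oscillation), and the ECAP denominator is floored at a
small epsilon instead of emitting infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WSSTimeSeries",
    "HemoFields",
    "integrate_series",
    "tawss",
    "osi",
    "ecap",
    "compute_hemo_fields",
    "transform_target",
    "inverse_transform_target",
    "load_wss_npz",
    "save_wss_npz",
    "load_wss_vtk_series",
]


@dataclass
class WSSTimeSeries:
    times: np.ndarray  # (K,) strictly increasing sample times, s
    values: np.ndarray  # (K, V, 3) WSS vectors, Pa
    period: float  # cycle duration T, s

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("need at least one sample time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.values.shape[0] != len(self.times) or self.values.shape[2] != 3:
            raise ValueError("values must have shape (K, V, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite WSS values")
        if self.durations().min() <= 0:
            raise ValueError("non-positive sample duration")

    def durations(self) -> np.ndarray:
        """Left-sample holding durations; the last sample wraps to t_1 + T."""
        t = self.times
        return np.concatenate([np.diff(t), [self.period - t[-1] + t[0]]])


@dataclass
class HemoFields:
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray


def integrate_series(series: WSSTimeSeries, rule: str = "step"):
    """Cycle-mean WSS vector and cycle-mean WSS magnitude per vertex."""
    dt = series.durations()
    if not np.isclose(dt.sum(), series.period, rtol=1e-9):
        raise ValueError("sample durations do not sum to the period")
    if rule == "step":
        w = dt
        vals = series.values
    elif rule == "trapezoid":
        # closed cycle: average consecutive samples, wrapping the last
        vals = 0.5 * (series.values + np.roll(series.values, -1, axis=0))
        w = dt
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    mean_vec = np.einsum("k,kvc->vc", w, vals) / series.period
    mean_mag = np.einsum("k,kv->v", w, np.linalg.norm(vals, axis=2)) / series.period
    return mean_vec, mean_mag


def tawss(series: WSSTimeSeries, rule: str = "step") -> np.ndarray:
    return integrate_series(series, rule)[1]


def osi(series: WSSTimeSeries, rule: str = "step") -> np.ndarray:
    mean_vec, mean_mag = integrate_series(series, rule)
    out = np.zeros_like(mean_mag)
    nz = mean_mag > 0
    out[nz] = 0.5 * (1.0 - np.linalg.norm(mean_vec[nz], axis=1) / mean_mag[nz])
    return np.clip(out, 0.0, 0.5)


def ecap(tawss_field: np.ndarray, osi_field: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    tawss_field = np.asarray(tawss_field, dtype=np.float64)
    osi_field = np.asarray(osi_field, dtype=np.float64)
    if tawss_field.shape != osi_field.shape:
        raise ValueError("TAWSS and OSI fields must have matching shapes")
    if np.any(tawss_field < 0):
        raise ValueError("negative TAWSS")
    return osi_field / np.maximum(tawss_field, eps)


def compute_hemo_fields(series: WSSTimeSeries, eps: float = 1e-8) -> HemoFields:
    t = tawss(series)
    o = osi(series)
    return HemoFields(tawss=t, osi=o, ecap=ecap(t, o, eps))


def transform_target(field: np.ndarray, mode: str = "log1p") -> np.ndarray:
    """Variance-stabilizing transform applied to skewed ECAP targets
    before training (log1p admits exact zeros)."""
    field = np.asarray(field, dtype=np.float64)
    if mode == "none":
        return field.copy()
    if mode == "log1p":
        if np.any(field < 0):
            raise ValueError("log1p transform requires a nonnegative field")
        return np.log1p(field)
    raise ValueError(f"unknown transform mode {mode!r}")


def inverse_transform_target(field: np.ndarray, mode: str = "log1p") -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if mode == "none":
        return field.copy()
    if mode == "log1p":
        return np.expm1(field)
    raise ValueError(f"unknown transform mode {mode!r}")


def load_wss_vtk_series(
    paths: list[str],
    times_csv: str,
    period: float,
    array_name: str = "WSS",
) -> WSSTimeSeries:
    """Assemble a series from an ordered list of VTK/VTP snapshots
    carrying a 3-vector point-data array, plus a CSV of `index,time`."""
    from .io import read_mesh

    times_map = {}
    with open(times_csv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("index"):
                continue
            idx, t = line.split(",")[:2]
            times_map[int(idx)] = float(t)
    times = np.array([times_map[i] for i in range(len(paths))])
    values = []
    for p in paths:
        mesh = read_mesh(p)
        arr = mesh.fields.get(array_name)
        if arr is None or np.asarray(arr).ndim != 2 or np.asarray(arr).shape[1] != 3:
            raise ValueError(f"{p}: missing 3-vector point array {array_name!r}")
        values.append(np.asarray(arr))
    return WSSTimeSeries(times=times, values=np.stack(values), period=period)


def save_wss_npz(series: WSSTimeSeries, path: str):
    np.savez(path, times=series.times, wss=series.values, period=series.period)


def load_wss_npz(path: str) -> WSSTimeSeries:
    with np.load(path) as npz:
        return WSSTimeSeries(npz["times"], npz["wss"], float(npz["period"]))
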