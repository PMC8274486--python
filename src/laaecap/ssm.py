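"""Truncated-PCA statistical shape model over corresponded meshes.

Each corresponded mesh is a point in R^{3V}; the model keeps the mean
shape Xbar, the leading M orthonormal eigenvectors W_i and eigenvalues
lambda_i of the sample covariance.  The coefficient convention is

    alpha_i = W_i^T (Y - Xbar) / lambda_i,
    X = Xbar + sum_i alpha_i lambda_i W_i,

i.e. projection divides by the eigenvalue and reconstruction multiplies
it back (an exact round trip for shapes inside the model span).  A
``scaling='sqrt'`` switch normalizes by sqrt(lambda) instead, giving
unit-variance coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh

log = logging.getLogger(__name__)

__all__ = ["ShapeModel", "fit_shape_model", "project", "reconstruct"]


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (3V,)
    components: np.ndarray  # (M, 3V) orthonormal rows
    eigenvalues: np.ndarray  # (M,) non-increasing, > 0
    template_faces: np.ndarray
    scaling: str = "eigenvalue"  # or "sqrt"

    @property
    def M(self) -> int:
        return len(self.eigenvalues)

    def explained_variance_ratio(self, total_variance: float | None = None) -> np.ndarray:
        tot = total_variance if total_variance is not None else self.eigenvalues.sum()
        return self.eigenvalues / tot

    def _scale(self) -> np.ndarray:
        return (
            self.eigenvalues if self.scaling == "eigenvalue" else np.sqrt(self.eigenvalues)
        )

    def save_npz(self, path: str):
        np.savez(
            path,
            mean=self.mean_shape,
            components=self.components,
            eigenvalues=self.eigenvalues,
            faces=self.template_faces,
            scaling=self.scaling,
        )

    @classmethod
    def load_npz(cls, path: str) -> "ShapeModel":
        with np.load(path) as z:
            return cls(
                mean_shape=z["mean"],
                components=z["components"],
                eigenvalues=z["eigenvalues"],
                template_faces=z["faces"],
                scaling=str(z["scaling"]),
            )


def _stack(shapes: list[SurfaceMesh]) -> np.ndarray:
    V = shapes[0].n_vertices
    faces = shapes[0].faces
    for i, s in enumerate(shapes[1:], start=1):
        if s.n_vertices != V or not np.array_equal(s.faces, faces):
            raise ValueError(f"shape {i} does not match the template topology")
    return np.stack([s.vertices.reshape(-1) for s in shapes])


def fit_shape_model(
    shapes: list[SurfaceMesh], M: int, scaling: str = "eigenvalue"
) -> ShapeModel:
    """PCA of the stacked (n, 3V) coordinate matrix.

    M is capped at min(requested, n - 1, 3V); eigenpairs come from the
    thin SVD of the centred data matrix (lambda = s^2 / (n - 1)).
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    X = _stack(shapes)
    n, d = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    cap = min(M, n - 1, d)
    if cap < M:
        log.warning("requested M=%d capped at %d (n=%d samples)", M, cap, n)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    keep = min(cap, int(np.sum(lam > 1e-12 * max(lam[0], 1.0))))
    return ShapeModel(
        mean_shape=mean,
        components=Vt[:keep],
        eigenvalues=lam[:keep],
        template_faces=shapes[0].faces.copy(),
        scaling=scaling,
    )


def project(shape: SurfaceMesh, model: ShapeModel) -> np.ndarray:
    """Shape coefficients alpha_i = W_i (Y - Xbar) / lambda_i."""
    if shape.n_vertices * 3 != model.mean_shape.size or not np.array_equal(
        shape.faces, model.template_faces
    ):
        raise ValueError("shape does not match the template topology")
    y = shape.vertices.reshape(-1) - model.mean_shape
    return (model.components @ y) / model._scale()


def reconstruct(alphas: np.ndarray, model: ShapeModel) -> SurfaceMesh:
    """X = Xbar + sum_i alpha_i lambda_i W_i with the template faces."""
    alphas = np.asarray(alphas, dtype=np.float64)
    if len(alphas) > model.M:
        raise ValueError("more coefficients than model components")
    x = model.mean_shape + (alphas * model._scale()[: len(alphas)]) @ model.components[
        : len(alphas)
    ]
    return SurfaceMesh(x.reshape(-1, 3), model.template_faces.copy())
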