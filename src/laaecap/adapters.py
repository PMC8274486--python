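"""Uniform train/predict adapters for the experiment drivers.

Each adapter wraps one surrogate family behind the same two calls
(`fit` on train+validation cases, `predict` per case), so k-fold and
sequential protocols are architecture-agnostic.
"""

from __future__ import annotations

import numpy as np

from . import fcn as fcn_mod
from . import geometric as geo
from .flatten import FlatMap, build_flat_map, sample_field, to_bullseye, unflatten
from .hemo import inverse_transform_target, transform_target
from .metrics import SurrogateAdapter
from .ssm import fit_shape_model, project
from .synthetic import Case
from .unet import UNet, UNetConfig, standardize_inputs, train_unet

__all__ = ["GeometricAdapter", "PCAFCNAdapter", "UNetAdapter", "make_adapter"]


class GeometricAdapter:
    name = "geometric"

    def __init__(self, config: geo.GeoNetConfig | None = None):
        self.config = config or geo.GeoNetConfig.reduced()
        self.model = None
        self.record = None

    def _sample(self, case: Case) -> geo.GraphSample:
        target = transform_target(case.ecap, self.config.target_transform)
        return geo.sample_from_mesh(
            case.mesh, target, self.record, self.config.kernel_size, case.case_id
        )

    def fit(self, train: list[Case], val: list[Case], seed: int) -> None:
        _, self.record = geo.preprocess_vertex_features([c.mesh for c in train])
        tr = [self._sample(c) for c in train]
        va = [self._sample(c) for c in val]
        self.model = geo.build_geometric_model(self.config, seed)
        geo.train_geometric(self.model, tr, va, self.config, seed)

    def predict(self, case: Case) -> np.ndarray:
        return geo.predict_geometric(
            self.model, case.mesh, self.record, self.config.target_transform
        )


class PCAFCNAdapter:
    name = "pca_fcn"

    def __init__(self, n_components: int = 32, config: fcn_mod.FCNConfig | None = None):
        self.n_components = n_components
        self.base_config = config
        self.model = None
        self.shape_model = None
        self.config = None

    def fit(self, train: list[Case], val: list[Case], seed: int) -> None:
        self.shape_model = fit_shape_model(
            [c.mesh for c in train], M=self.n_components
        )
        M = self.shape_model.M
        V = train[0].mesh.n_vertices
        base = self.base_config or fcn_mod.FCNConfig()
        self.config = fcn_mod.FCNConfig(
            input_dim=M,
            hidden=base.hidden,
            output_dim=V,
            activation=base.activation,
            dropout=base.dropout,
            lr=base.lr,
            epochs=base.epochs,
            loss=base.loss,
        )
        Xtr = np.stack([project(c.mesh, self.shape_model) for c in train])
        Ytr = np.stack([c.ecap for c in train])
        Xva = np.stack([project(c.mesh, self.shape_model) for c in val])
        Yva = np.stack([c.ecap for c in val])
        self.model = fcn_mod.build_fcn(self.config, seed)
        fcn_mod.train_fcn(self.model, (Xtr, Ytr), (Xva, Yva), self.config, seed)

    def predict(self, case: Case) -> np.ndarray:
        return fcn_mod.predict_fcn(self.model, project(case.mesh, self.shape_model))


def bullseye_to_grid(image: np.ndarray, flat: FlatMap) -> np.ndarray:
    """Sample an (S, S) bull's-eye image back onto the (R, A) grid."""
    S = image.shape[0]
    R, A = flat.grid_shape
    rho = 1.0 - flat.d_levels  # apex at the centre
    th = flat.theta
    rr, tt = np.meshgrid(rho, th, indexing="ij")
    cx = (S - 1) / 2.0
    x = rr * np.cos(tt) * (S / 2.0) + cx
    y = rr * np.sin(tt) * (S / 2.0) + cx
    x0 = np.clip(np.floor(x).astype(int), 0, S - 1)
    y0 = np.clip(np.floor(y).astype(int), 0, S - 1)
    x1 = np.minimum(x0 + 1, S - 1)
    y1 = np.minimum(y0 + 1, S - 1)
    wx = np.clip(x - x0, 0, 1)
    wy = np.clip(y - y0, 0, 1)
    return (
        image[y0, x0] * (1 - wx) * (1 - wy)
        + image[y0, x1] * wx * (1 - wy)
        + image[y1, x0] * (1 - wx) * wy
        + image[y1, x1] * wx * wy
    )


class UNetAdapter:
    name = "unet"

    def __init__(
        self,
        style: str = "bullseye",  # or "cartesian"
        R: int = 32,
        A: int = 32,
        S: int = 32,
        config: UNetConfig | None = None,
        target_transform: str = "none",
    ):
        if style not in ("bullseye", "cartesian"):
            raise ValueError(f"unknown style {style!r}")
        self.style = style
        self.R, self.A, self.S = R, A, S
        side = S if style == "bullseye" else max(R, A)
        depth = int(np.log2(side))
        self.config = config or UNetConfig(
            depth=min(depth, 5),
            base_channels=8,
            epochs=60,
            circular_w=(style == "cartesian"),
        )
        self.target_transform = target_transform
        self.model: UNet | None = None
        self.record = None
        self._flat_cache: dict[str, FlatMap] = {}

    def _flat(self, case: Case) -> FlatMap:
        if case.case_id not in self._flat_cache:
            self._flat_cache[case.case_id] = build_flat_map(
                case.mesh, case.dist, case.mesh.landmark, self.R, self.A
            )
        return self._flat_cache[case.case_id]

    def _images(self, case: Case):
        flat = self._flat(case)
        tgt_grid = sample_field(
            transform_target(case.ecap, self.target_transform), case.mesh, flat
        )
        if self.style == "cartesian":
            img = np.moveaxis(flat.channels, -1, 0)  # (3, R, A)
            tgt = tgt_grid[None]
            mask = np.ones(tgt_grid.shape, dtype=bool)
        else:
            be = to_bullseye(flat, self.S, flat.channels)
            img = np.moveaxis(be.image, -1, 0)
            tgt = to_bullseye(flat, self.S, tgt_grid).image[None, :, :, 0]
            mask = be.mask
        return img, tgt, mask

    def fit(self, train: list[Case], val: list[Case], seed: int) -> None:
        def bundle(cases):
            imgs, tgts, masks = zip(*(self._images(c) for c in cases))
            return np.stack(imgs), np.stack(tgts), np.stack(masks)

        Xtr, Ytr, Mtr = bundle(train)
        Xva, Yva, Mva = bundle(val)
        Xtr, self.record = standardize_inputs(Xtr, Mtr)
        Xva = self.record.apply(Xva)
        self.model = UNet(self.config, seed)
        train_unet(self.model, (Xtr, Ytr, Mtr), (Xva, Yva, Mva), self.config, seed)

    def predict(self, case: Case) -> np.ndarray:
        from .nn import Tensor

        flat = self._flat(case)
        img, _, mask = self._images(case)
        x = self.record.apply(img[None])
        self.model.eval()
        pred = self.model(Tensor(x)).data[0, 0]
        if self.style == "cartesian":
            grid = pred
        else:
            grid = bullseye_to_grid(pred, flat)
        field = unflatten(case.mesh, flat, grid)
        return inverse_transform_target(field, self.target_transform)


def make_adapter(arch: str, **kwargs) -> SurrogateAdapter:
    if arch == "geometric":
        return GeometricAdapter(**kwargs)
    if arch == "pca_fcn":
        return PCAFCNAdapter(**kwargs)
    if arch == "unet_bullseye":
        return UNetAdapter(style="bullseye", **kwargs)
    if arch == "unet_cartesian":
        return UNetAdapter(style="cartesian", **kwargs)
    raise ValueError(f"unknown architecture {arch!r}")
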