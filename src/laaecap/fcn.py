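"""Fully connected regressor from PCA shape coefficients to per-vertex
ECAP on the registered template.

The default architecture widens layer by layer
(32 -> 128 -> 256 -> 512 -> 1024 -> 2048 -> template vertices), with
ReLU + dropout after every hidden layer and a linear output; trained
with Adam on an L1 loss, keeping the parameter state with the best
validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Dropout, Linear, Module, Tensor

__all__ = ["FCNConfig", "FCNRegressor", "build_fcn", "train_fcn", "predict_fcn"]

TEMPLATE_VERTICES = 2466  # registered LAA template size


@dataclass
class FCNConfig:
    input_dim: int = 32
    hidden: list[int] = field(default_factory=lambda: [128, 256, 512, 1024, 2048])
    output_dim: int = TEMPLATE_VERTICES
    activation: str = "relu"
    dropout: float = 0.1
    lr: float = 0.01
    epochs: int = 150
    loss: str = "l1"

    def __post_init__(self):
        if not self.hidden:
            raise ValueError("need at least one hidden layer")
        if any(w < 1 for w in self.hidden):
            raise ValueError("hidden widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


class FCNRegressor(Module):
    def __init__(self, config: FCNConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        dims = [config.input_dim] + list(config.hidden) + [config.output_dim]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.drops = [Dropout(config.dropout, rng) for _ in config.hidden]
        self.config = config

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers[:-1]):
            x = layer(x)
            x = x.relu() if self.config.activation == "relu" else x.elu()
            x = self.drops[i](x)
        return self.layers[-1](x)


def build_fcn(config: FCNConfig, seed: int = 0) -> FCNRegressor:
    return FCNRegressor(config, seed)


def _loss(pred: Tensor, target: Tensor, kind: str) -> Tensor:
    diff = pred - target
    if kind == "l1":
        return diff.abs().mean()
    if kind == "l2":
        return (diff * diff).mean()
    if kind == "smooth_l1":
        d = np.abs(diff.data)
        # piecewise: quadratic below 1, linear above — assembled per element
        quad = (diff * diff) * 0.5
        lin = diff.abs() - 0.5
        mask = (d < 1.0).astype(float)
        return (quad * Tensor(mask) + lin * Tensor(1.0 - mask)).mean()
    raise ValueError(f"unknown loss {kind!r}")


def train_fcn(
    model: FCNRegressor,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: FCNConfig | None = None,
    seed: int = 0,
):
    """Adam training with best-validation checkpoint selection.

    `train`/`val` are (alphas (n, M), targets (n, output_dim)) pairs.
    Returns (model, history) where history maps epoch -> train/val loss.
    Deterministic for a given seed.
    """
    config = config or model.config
    Xtr, Ytr = map(np.asarray, train)
    Xva, Yva = map(np.asarray, val)
    if len(Xtr) < 2:
        raise ValueError("need at least two training pairs")
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed)
    history = {"train": [], "val": []}
    best_val, best_state = np.inf, model.state_dict()
    for _ in range(config.epochs):
        model.train()
        perm = rng.permutation(len(Xtr))
        out = model(Tensor(Xtr[perm]))
        loss = _loss(out, Tensor(Ytr[perm]), config.loss)
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite training loss")
        model.zero_grad()
        loss.backward()
        opt.step()
        model.eval()
        val_loss = float(_loss(model(Tensor(Xva)), Tensor(Yva), config.loss).data)
        history["train"].append(float(loss.data))
        history["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict_fcn(model: FCNRegressor, alphas: np.ndarray) -> np.ndarray:
    alphas = np.asarray(alphas, dtype=np.float64)
    single = alphas.ndim == 1
    alphas = np.atleast_2d(alphas)
    if alphas.shape[1] != model.config.input_dim:
        raise ValueError(
            f"expected {model.config.input_dim} coefficients, got {alphas.shape[1]}"
        )
    model.eval()
    out = model(Tensor(alphas)).data
    return out[0] if single else out
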