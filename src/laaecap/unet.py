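"""Encoder-decoder image surrogate over flattened LAA maps.

Input is the 3-channel xyz image produced by flattening (bull's-eye or
Cartesian); output is a 1-channel ECAP image.  Each of the `depth`
encoder blocks halves the resolution with a stride-2 convolution
followed by batch normalization and ReLU; the decoder mirrors it with
nearest-neighbour upsampling and skip concatenation, ending in a linear
1x1 convolution.  The training loss is an L1 restricted to the validity
mask, so padded pixels outside the bull's-eye disc never contribute.

For Cartesian maps the angular axis wraps; circular padding along that
axis is available (default on) to remove the convolution seam at the
0/360 degree cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, BatchNorm2d, Conv2d, Dropout, Module, Tensor, Upsample2x, concat

__all__ = [
    "UNetConfig",
    "UNet",
    "build_unet",
    "masked_l1",
    "standardize_inputs",
    "StandardizeRecord",
    "train_unet",
]


@dataclass
class UNetConfig:
    depth: int = 7
    base_channels: int = 32
    in_channels: int = 3
    out_channels: int = 1
    channel_cap_factor: int = 8  # widths double per block up to this cap
    lr: float = 0.0005
    epochs: int = 300
    batch_size: int = 8
    loss: str = "l1"
    dropout: float = 0.1
    circular_w: bool = False  # circular padding along the angle axis

    def required_divisor(self) -> int:
        return 2**self.depth


class UNet(Module):
    def __init__(self, config: UNetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        cap = config.base_channels * config.channel_cap_factor
        widths = [min(config.base_channels * 2**i, cap) for i in range(config.depth)]
        enc, bns = [], []
        cin = config.in_channels
        for w in widths:
            enc.append(
                Conv2d(cin, w, 4, rng, stride=2, pad=1, circular_w=config.circular_w)
            )
            bns.append(BatchNorm2d(w))
            cin = w
        self.enc = enc
        self.enc_bn = bns
        dec, dbns = [], []
        for i in range(config.depth - 2, -1, -1):
            # upsampled deeper features concatenated with the skip at level i
            cin_dec = widths[i + 1] + widths[i]
            dec.append(
                Conv2d(cin_dec, widths[i], 3, rng, stride=1, pad=1, circular_w=config.circular_w)
            )
            dbns.append(BatchNorm2d(widths[i]))
        self.dec = dec
        self.dec_bn = dbns
        self.up = Upsample2x()
        self.final_up = Upsample2x()
        self.final_conv = Conv2d(
            widths[0], widths[0], 3, rng, stride=1, pad=1, circular_w=config.circular_w
        )
        self.final_bn = BatchNorm2d(widths[0])
        self.out_conv = Conv2d(widths[0], config.out_channels, 1, rng)
        self.drop = Dropout(config.dropout, rng)
        self.widths = widths

    def forward(self, x: Tensor) -> Tensor:
        s = x.shape[2]
        div = self.config.required_divisor()
        if s % div or x.shape[3] % div:
            raise ValueError(
                f"input spatial size must be divisible by 2**depth = {div}"
            )
        skips = []
        for conv, bn in zip(self.enc, self.enc_bn):
            x = bn(conv(x)).relu()
            skips.append(x)
        y = skips[-1]
        for j, (conv, bn) in enumerate(zip(self.dec, self.dec_bn)):
            level = self.config.depth - 2 - j
            y = self.up(y)
            y = concat([y, skips[level]], axis=1)
            y = self.drop(bn(conv(y)).relu())
        y = self.final_up(y)
        y = self.final_bn(self.final_conv(y)).relu()
        return self.out_conv(y)


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(config or UNetConfig(), seed)


def masked_l1(pred, target, mask) -> Tensor:
    """Mean absolute error over mask-true pixels only.

    Accepts Tensors or arrays; broadcasting a (H, W) mask over channel
    and batch axes is allowed.
    """
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = target if isinstance(target, Tensor) else Tensor(target)
    m = np.broadcast_to(np.asarray(mask, dtype=np.float64), pred.shape)
    n_true = m.sum()
    if n_true == 0:
        raise ValueError("mask has no true pixels")
    return ((pred - target).abs() * Tensor(m)).sum() * (1.0 / n_true)


@dataclass
class StandardizeRecord:
    mean: np.ndarray  # (C,)
    std: np.ndarray  # (C,)

    def apply(self, images: np.ndarray) -> np.ndarray:
        return (images - self.mean[None, :, None, None]) / self.std[None, :, None, None]


def standardize_inputs(images: np.ndarray, masks: np.ndarray):
    """Per-channel z-scoring of (N, C, H, W) images with statistics from
    mask-true training pixels only; returns (standardized, record)."""
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=bool)
    N, C, H, W = images.shape
    sel = np.broadcast_to(masks[:, None, :, :], images.shape)
    mean = np.zeros(C)
    std = np.zeros(C)
    for c in range(C):
        vals = images[:, c][masks]
        mean[c] = vals.mean()
        std[c] = vals.std()
    if np.any(std == 0):
        raise ValueError(f"zero-variance channel(s): {np.flatnonzero(std == 0).tolist()}")
    rec = StandardizeRecord(mean=mean, std=std)
    return rec.apply(images), rec


def train_unet(
    model: UNet,
    train: tuple[np.ndarray, np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: UNetConfig | None = None,
    seed: int = 0,
):
    """Adam + masked L1 with best-validation checkpoint selection.

    `train`/`val` are (images (N, C, H, W), targets (N, 1, H, W),
    masks (N, H, W)) triples of already standardized inputs.
    """
    config = config or model.config
    Xtr, Ytr, Mtr = train
    Xva, Yva, Mva = val
    if len(Xtr) < 2:
        raise ValueError("need at least two training images")
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed)
    history = {"train": [], "val": []}
    best_val, best_state = np.inf, model.state_dict()
    B = max(1, config.batch_size)
    for _ in range(config.epochs):
        model.train()
        perm = rng.permutation(len(Xtr))
        ep = 0.0
        for b0 in range(0, len(Xtr), B):
            idx = perm[b0 : b0 + B]
            pred = model(Tensor(Xtr[idx]))
            loss = masked_l1(pred, Tensor(Ytr[idx]), Mtr[idx][:, None, :, :])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            model.zero_grad()
            loss.backward()
            opt.step()
            ep += float(loss.data) * len(idx)
        model.eval()
        vp = model(Tensor(Xva))
        vl = float(masked_l1(vp, Tensor(Yva), Mva[:, None, :, :]).data)
        history["train"].append(ep / len(Xtr))
        history["val"].append(vl)
        if vl < best_val:
            best_val = vl
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, history
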