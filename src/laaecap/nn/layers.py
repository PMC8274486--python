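"""Neural-network building blocks on top of the autodiff engine.

Includes dense layers, batch-norm, dropout, strided 2-D convolutions
(im2col), nearest-neighbour upsampling and the continuous B-spline graph
convolution used by the geometric surrogate.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Dropout",
    "BatchNorm2d",
    "Conv2d",
    "Upsample2x",
    "SplineConv",
]


class Module:
    """Base class: parameter registration, counting and (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, flag: bool = True):
        self.training = flag
        for m in self._modules.values():
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        for k, v in state.items():
            params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), True)
        self.bias = Tensor(np.zeros(out_dim), True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class BatchNorm2d(Module):
    """Batch normalization over (N, C, H, W) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), True)
        self.beta = Tensor(np.zeros(channels), True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


def _conv_forward(x, w, stride, pad, circular_w):
    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    ph, pw = pad
    mode_w = "wrap" if circular_w else "constant"
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (0, 0)), mode="constant")
    xp = np.pad(xp, ((0, 0), (0, 0), (0, 0), (pw, pw)), mode=mode_w)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sN, sC, sH, sW = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sN, sC, sH, sW, sH * stride, sW * stride),
    )
    cols = win.reshape(n, c * kh * kw, ho * wo)
    out = np.einsum("of,nfl->nol", w.reshape(co, -1), cols, optimize=True)
    return out.reshape(n, co, ho, wo), cols, (hp, wp, ho, wo)


class Conv2d(Module):
    """2-D convolution; optional circular padding along the width axis
    (used for the angular axis of Cartesian flattened maps)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        circular_w: bool = False,
    ):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _glorot(rng, fan_in, out_ch, (out_ch, in_ch, kernel, kernel)), True
        )
        self.bias = Tensor(np.zeros(out_ch), True)
        self.stride = stride
        self.pad = pad
        self.circular_w = circular_w

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        stride, ph = self.stride, self.pad
        pw = self.pad
        out_data, cols, (hp, wp, ho, wo) = _conv_forward(
            x.data, w.data, stride, (ph, pw), self.circular_w
        )
        n, c, h, wd = x.data.shape
        co, ci, kh, kw = w.data.shape

        out = Tensor(out_data)
        if x.requires_grad or w.requires_grad:
            out.requires_grad = True
            out._parents = (x, w)
            # flat indices of each im2col entry in the padded image
            ic, ikh, ikw = np.meshgrid(
                np.arange(c), np.arange(kh), np.arange(kw), indexing="ij"
            )
            iho, iwo = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
            rows = ikh.reshape(-1, 1) + iho.reshape(1, -1) * stride
            colsx = ikw.reshape(-1, 1) + iwo.reshape(1, -1) * stride
            chan = np.broadcast_to(ic.reshape(-1, 1), rows.shape)
            flat_idx = (chan * hp + rows) * wp + colsx  # (c*kh*kw, ho*wo)

            circular = self.circular_w

            def bw(g, _):
                gr = g.reshape(n, co, ho * wo)
                if w.requires_grad:
                    dw = np.einsum("nol,nfl->of", gr, cols, optimize=True)
                    w._accum(dw.reshape(w.data.shape))
                if x.requires_grad:
                    dcols = np.einsum(
                        "of,nol->nfl", w.data.reshape(co, -1), gr, optimize=True
                    )
                    dxp = np.zeros((n, c * hp * wp))
                    fi = flat_idx.ravel()
                    for b in range(n):
                        np.add.at(dxp[b], fi, dcols[b].ravel())
                    dxp = dxp.reshape(n, c, hp, wp)
                    dx = dxp[:, :, ph : ph + h, pw : pw + wd].copy()
                    if pw > 0:
                        if circular:
                            dx[:, :, :, :pw] += dxp[:, :, ph : ph + h, wd + pw :]
                            dx[:, :, :, wd - pw :] += dxp[:, :, ph : ph + h, :pw]
                        # zero padding: discarded
                    dx = dx[:, :, :, :]
                    x._accum(dx)

            out._backward = bw
        return out + self.bias.reshape(1, -1, 1, 1)


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: Tensor) -> Tensor:
        data = x.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(data)
        if x.requires_grad:
            out.requires_grad = True
            out._parents = (x,)

            def bw(g, _):
                n, c, h2, w2 = g.shape
                x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

            out._backward = bw
        return out


def spline_mix(msg: Tensor, weights: Tensor, basis_idx: np.ndarray, basis_w: np.ndarray) -> Tensor:
    """Per-edge kernel mix: out_e = sum_p b[e,p] * msg_e @ W[idx[e,p]].

    `basis_idx`/`basis_w` are the (E, P) active tensor-product B-spline
    kernel indices and weights for each directed edge.
    """
    E, P = basis_idx.shape
    out_dim = weights.data.shape[2]
    acc = np.zeros((E, out_dim))
    for p in range(P):
        wg = weights.data[basis_idx[:, p]]  # (E, in, out)
        acc += basis_w[:, p, None] * np.einsum("ei,eio->eo", msg.data, wg, optimize=True)
    out = Tensor(acc)
    if msg.requires_grad or weights.requires_grad:
        out.requires_grad = True
        out._parents = (msg, weights)

        def bw(g, _):
            if msg.requires_grad:
                dm = np.zeros_like(msg.data)
                for p in range(P):
                    wg = weights.data[basis_idx[:, p]]
                    dm += basis_w[:, p, None] * np.einsum(
                        "eo,eio->ei", g, wg, optimize=True
                    )
                msg._accum(dm)
            if weights.requires_grad:
                dw = np.zeros_like(weights.data)
                for p in range(P):
                    contrib = np.einsum(
                        "e,ei,eo->eio", basis_w[:, p], msg.data, g, optimize=True
                    )
                    np.add.at(dw, basis_idx[:, p], contrib)
                weights._accum(dw)

        out._backward = bw
    return out


class SplineConv(Module):
    """Continuous B-spline kernel convolution over a mesh graph.

    Aggregation is the mean over in-neighbours; a root weight transforms
    the centre vertex and a bias closes the layer.  The kernel holds
    ``kernel_size**dim`` weight matrices steered by edge pseudo-coordinates.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        dim: int = 3,
        kernel_size: int = 5,
        degree: int = 1,
    ):
        super().__init__()
        if degree != 1:
            raise NotImplementedError("only degree-1 B-spline bases are supported")
        if kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        K = kernel_size**dim
        self.kernel_size = kernel_size
        self.dim = dim
        self.degree = degree
        self.weights = Tensor(_glorot(rng, in_dim, out_dim, (K, in_dim, out_dim)), True)
        self.root = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), True)
        self.bias = Tensor(np.zeros(out_dim), True)

    def forward(self, feats: Tensor, graph_support) -> Tensor:
        """`graph_support` carries (src, dst, basis_idx, basis_w, inv_deg, V)."""
        src, dst, basis_idx, basis_w, inv_deg, V = graph_support
        if len(src):
            msg = feats.gather(src)
            mixed = spline_mix(msg, self.weights, basis_idx, basis_w)
            agg = mixed.segment_sum(dst, V) * Tensor(inv_deg[:, None])
            return agg + feats @ self.root + self.bias
        return feats @ self.root + self.bias
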