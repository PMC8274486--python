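"""Autodiff engine and layer-level checks (gradients vs finite
differences, spline kernel basics, convolution plumbing)."""

import numpy as np
import pytest

from laaecap.geometric import build_graph_support, spline_basis
from laaecap.mesh import MeshGraph
from laaecap.nn import BatchNorm2d, Conv2d, Linear, SplineConv, Tensor, concat
from laaecap.nn.layers import spline_mix


def numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return g


class TestAutograd:
    def test_mlp_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        l1, l2 = Linear(4, 6, rng), Linear(6, 2, rng)
        x = rng.random((5, 4))
        y = rng.random((5, 2))

        def loss_of_weight(w):
            l1.weight.data = w
            out = l2(l1(Tensor(x)).elu())
            return float(((out - Tensor(y)) ** 2).sum().data)

        w0 = l1.weight.data.copy()
        xt = Tensor(x, True)
        out = l2(l1(xt).elu())
        loss = ((out - Tensor(y)) ** 2).sum()
        loss.backward()
        analytic = l1.weight.grad.copy()
        num = numeric_grad(loss_of_weight, w0)
        l1.weight.data = w0
        assert np.abs(analytic - num).max() < 1e-5

    def test_broadcast_add_mul_backward(self):
        a = Tensor(np.ones((3, 4)), True)
        b = Tensor(np.arange(4.0), True)
        ((a * b + b) ** 2).sum().backward()
        # d/db of sum((b(a+1))^2) with a=1 -> sum over rows of 2*(2b)*2
        assert np.allclose(b.grad, 3 * 2 * (2 * np.arange(4.0)) * 2)
        assert np.allclose(a.grad, 2 * (np.arange(4.0) * 2)[None] * np.arange(4.0)[None])

    def test_max_reduction_routes_gradient(self):
        x = Tensor(np.array([[1.0, 5.0, 2.0], [7.0, 0.0, 3.0]]), True)
        x.max(axis=0).sum().backward()
        assert np.array_equal(x.grad, [[0, 1, 0], [1, 0, 1]])

    def test_concat_backward_splits(self):
        a = Tensor(np.ones((2, 2)), True)
        b = Tensor(np.ones((2, 3)), True)
        (concat([a, b], axis=1) * 2).sum().backward()
        assert np.allclose(a.grad, 2) and np.allclose(b.grad, 2)

    def test_gather_segment_sum_adjoint(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.random((4, 3)), True)
        idx = np.array([0, 2, 2, 3, 1])
        y = x.gather(idx).segment_sum(np.array([0, 0, 1, 1, 1]), 2)
        (y * y).sum().backward()

        def f(xv):
            g = xv[idx]
            out = np.zeros((2, 3))
            np.add.at(out, [0, 0, 1, 1, 1], g)
            return float((out**2).sum())

        assert np.abs(x.grad - numeric_grad(f, x.data.copy())).max() < 1e-5


class TestConv2d:
    def test_gradcheck(self):
        rng = np.random.default_rng(2)
        conv = Conv2d(2, 3, 3, rng, stride=2, pad=1)
        x = rng.random((2, 2, 6, 6))

        def loss_w(w):
            conv.weight.data = w
            return float((conv(Tensor(x)) ** 2).sum().data)

        w0 = conv.weight.data.copy()
        xt = Tensor(x, True)
        (conv(xt) ** 2).sum().backward()
        gw = conv.weight.grad.copy()
        gx = xt.grad.copy()
        assert np.abs(gw - numeric_grad(loss_w, w0)).max() < 1e-4
        conv.weight.data = w0

        def loss_x(xv):
            return float((conv(Tensor(xv)) ** 2).sum().data)

        assert np.abs(gx - numeric_grad(loss_x, x.copy())).max() < 1e-4

    def test_circular_padding_wraps(self):
        rng = np.random.default_rng(3)
        conv = Conv2d(1, 1, 3, rng, stride=1, pad=1, circular_w=True)
        x = rng.random((1, 1, 4, 8))
        rolled = np.roll(x, 2, axis=3)
        y0 = conv(Tensor(x)).data
        y1 = conv(Tensor(rolled)).data
        # interior rows are circularly equivariant along the width axis
        assert np.abs(np.roll(y0, 2, axis=3)[:, :, 1:-1] - y1[:, :, 1:-1]).max() < 1e-12

    def test_batchnorm_normalizes(self):
        bn = BatchNorm2d(3)
        x = np.random.default_rng(4).random((4, 3, 5, 5)) * 7 + 3
        y = bn(Tensor(x)).data
        assert np.abs(y.mean(axis=(0, 2, 3))).max() < 1e-6
        assert np.abs(y.std(axis=(0, 2, 3)) - 1).max() < 1e-3


class TestSplineBasis:
    @pytest.mark.parametrize(
        "u,k,idx,w",
        [
            (0.0, 5, [0], [1.0]),
            (1.0, 5, [4], [1.0]),
            (0.1, 5, [0, 1], [0.6, 0.4]),
        ],
    )
    def test_examples(self, u, k, idx, w):
        i, ww = spline_basis(u, k)
        assert list(i) == idx
        assert np.allclose(ww, w)

    def test_partition_of_unity(self):
        for u in np.linspace(0, 1, 33):
            _, w = spline_basis(float(u), 5)
            assert np.isclose(w.sum(), 1.0)


def five_node_graph(seed=0):
    rng = np.random.default_rng(seed)
    und = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 0], [0, 2], [1, 3]])
    edges = np.vstack([und, und[:, ::-1]])
    return MeshGraph(5, edges, rng.random((len(edges), 3))), rng


class TestSplineConv:
    def test_matches_brute_force_dense(self):
        graph, rng = five_node_graph(0)
        sup = build_graph_support(graph, 5)
        conv = SplineConv(4, 3, rng)
        f = rng.random((5, 4))
        out = conv(Tensor(f), sup.as_tuple()).data

        k = 5
        deg = np.bincount(graph.edges[:, 1], minlength=5)
        bf = np.zeros((5, 3))
        for e, (a, b) in enumerate(graph.edges):
            w1 = [np.zeros(k) for _ in range(3)]
            for d in range(3):
                i, w = spline_basis(float(graph.pseudo_coords[e, d]), k)
                w1[d][i] = w
            for ix in range(k):
                for iy in range(k):
                    for iz in range(k):
                        Bp = w1[0][ix] * w1[1][iy] * w1[2][iz]
                        if Bp:
                            bf[b] += Bp * (f[a] @ conv.weights.data[ix * 25 + iy * 5 + iz])
        bf = bf / deg[:, None] + f @ conv.root.data + conv.bias.data
        assert np.abs(out - bf).max() < 1e-6

    def test_partition_of_unity_reduces_to_mean(self):
        graph, rng = five_node_graph(1)
        sup = build_graph_support(graph, 5)
        conv = SplineConv(4, 3, rng)
        W = rng.random((4, 3))
        conv.weights.data[:] = W  # every kernel weight equal
        conv.root.data[:] = 0.0
        conv.bias.data[:] = 0.0
        f = rng.random((5, 4))
        out = conv(Tensor(f), sup.as_tuple()).data
        expected = np.zeros((5, 3))
        deg = np.bincount(graph.edges[:, 1], minlength=5)
        for a, b in graph.edges:
            expected[b] += f[a] @ W
        expected /= deg[:, None]
        assert np.abs(out - expected).max() < 1e-9

    def test_gradient_check(self):
        graph, rng = five_node_graph(2)
        sup = build_graph_support(graph, 5)
        conv = SplineConv(3, 2, rng)
        f = rng.random((5, 3))
        ft = Tensor(f, True)
        (conv(ft, sup.as_tuple()) ** 2).sum().backward()

        def loss_x(xv):
            return float((conv(Tensor(xv), sup.as_tuple()) ** 2).sum().data)

        assert np.abs(ft.grad - numeric_grad(loss_x, f.copy())).max() < 1e-4

    def test_fused_path_equals_reference(self):
        from laaecap.geometric import _fused_spline_conv

        graph, rng = five_node_graph(3)
        sup = build_graph_support(graph, 5)
        conv = SplineConv(4, 4, rng)
        f = rng.random((5, 4))
        ref = conv(Tensor(f), sup.as_tuple()).data
        fused = _fused_spline_conv(Tensor(f), conv, sup).data
        assert np.abs(ref - fused).max() < 1e-12

    def test_isolated_node_gets_root_plus_bias(self):
        rng = np.random.default_rng(4)
        conv = SplineConv(3, 2, rng)
        f = rng.random((1, 3))
        sup = (np.zeros(0, int), np.zeros(0, int), None, None, np.ones(1), 1)
        out = conv(Tensor(f), sup).data
        assert np.allclose(out, f @ conv.root.data + conv.bias.data)
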