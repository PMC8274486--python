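import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laaecap.hemo import (
    WSSTimeSeries,
    ecap,
    integrate_series,
    inverse_transform_target,
    osi,
    tawss,
    transform_target,
)


def series(vectors, period=1.0):
    """Equal-duration step series from a list of per-phase vectors."""
    K = len(vectors)
    times = np.arange(K) * (period / K)
    values = np.array(vectors, dtype=float)[:, None, :]
    return WSSTimeSeries(times=times, values=values, period=period)


class TestIntegration:
    def test_constant_series(self):
        mv, mm = integrate_series(series([[1, 0, 0]]))
        assert np.allclose(mv, [[1, 0, 0]]) and np.allclose(mm, 1.0)

    def test_symmetric_reversal(self):
        mv, mm = integrate_series(series([[1, 0, 0], [-1, 0, 0]]))
        assert np.allclose(mv, 0.0) and np.allclose(mm, 1.0)

    def test_orthogonal_halves(self):
        mv, mm = integrate_series(series([[1, 0, 0], [0, 1, 0]]))
        assert np.allclose(mv, [[0.5, 0.5, 0]]) and np.allclose(mm, 1.0)

    def test_bad_period_rejected(self):
        # sample window longer than the stated cycle -> negative wrap duration
        with pytest.raises(ValueError):
            WSSTimeSeries(
                times=np.array([0.0, 0.9]),
                values=np.zeros((2, 1, 3)),
                period=0.5,
            )

    def test_dense_quadrature_oracle(self):
        """Step-rule result is exact for step inputs: a 10000-point
        dense subsampling of the same step waveform agrees to 1e-12."""
        phases = [[1.2, 0, 0], [0.3, -0.4, 0], [-1, 0.5, 0.1], [0, 0, 2]]
        s = series(phases)
        K = 10000
        t_dense = np.arange(K) / K
        vals = np.array(phases)[np.minimum((t_dense * 4).astype(int), 3)][:, None, :]
        dense = WSSTimeSeries(times=t_dense, values=vals, period=1.0)
        for f in (tawss, osi):
            assert np.abs(f(s) - f(dense)).max() < 1e-12


class TestTawss:
    def test_constant_magnitude(self):
        assert np.allclose(tawss(series([[3, 4, 0]])), 5.0)

    def test_two_phase_average(self):
        assert np.allclose(tawss(series([[2, 0, 0], [0, 1, 0]])), 1.5)

    def test_zero_series(self):
        assert np.allclose(tawss(series([[0, 0, 0]])), 0.0)


class TestOsi:
    def test_constant_direction_zero(self):
        assert np.allclose(osi(series([[1, 0, 0], [2, 0, 0]])), 0.0)

    def test_perfect_reversal_half(self):
        assert np.allclose(osi(series([[1, 0, 0], [-1, 0, 0]])), 0.5)

    def test_orthogonal_halves(self):
        expected = 0.5 * (1 - np.sqrt(2) / 2)
        assert np.allclose(osi(series([[1, 0, 0], [0, 1, 0]])), expected)

    def test_zero_series_convention(self):
        assert np.allclose(osi(series([[0, 0, 0]])), 0.0)


class TestEcap:
    def test_direct_ratio(self):
        assert np.allclose(ecap(np.array([1.0]), np.array([0.5])), 0.5)

    def test_zero_osi(self):
        assert np.allclose(ecap(np.array([7.3]), np.array([0.0])), 0.0)

    def test_floored_denominator(self):
        assert np.allclose(ecap(np.array([0.0]), np.array([0.3]), eps=1e-8), 3.0e7)

    def test_negative_tawss_rejected(self):
        with pytest.raises(ValueError):
            ecap(np.array([-1.0]), np.array([0.1]))


class TestTransforms:
    def test_log1p_values(self):
        x = np.array([0.0, np.e - 1.0])
        assert np.allclose(transform_target(x, "log1p"), [0.0, 1.0])

    def test_roundtrip(self):
        x = np.random.default_rng(0).random(100) * 10
        back = inverse_transform_target(transform_target(x, "log1p"), "log1p")
        assert np.abs(back - x).max() < 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_target(np.array([-0.1]), "log1p")

    def test_log1p_reduces_lognormal_skewness(self):
        from scipy.stats import skew

        x = np.random.default_rng(42).lognormal(0.0, 1.0, 10000)
        assert skew(transform_target(x, "log1p")) < skew(x)


def test_vtk_series_roundtrip(tmp_path, small_laa):
    from laaecap.hemo import compute_hemo_fields, load_wss_vtk_series
    from laaecap.io import write_mesh

    rng = np.random.default_rng(0)
    V = small_laa.n_vertices
    snaps = rng.normal(size=(3, V, 3))
    paths = []
    for k in range(3):
        small_laa.fields["WSS"] = snaps[k]
        p = str(tmp_path / f"snap_{k}.vtp")
        write_mesh(small_laa, p)
        paths.append(p)
    (tmp_path / "times.csv").write_text("index,time\n0,0.0\n1,0.3\n2,0.6\n")
    s = load_wss_vtk_series(paths, str(tmp_path / "times.csv"), period=1.0)
    assert np.allclose(s.values, snaps)
    hf = compute_hemo_fields(s)
    assert hf.osi.max() <= 0.5 and hf.tawss.min() >= 0


@st.composite
def random_series(draw):
    K = draw(st.integers(2, 6))
    V = draw(st.integers(1, 4))
    vals = draw(
        st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=K * V * 3, max_size=K * V * 3
        )
    )
    values = np.array(vals).reshape(K, V, 3)
    times = np.arange(K) / K
    return WSSTimeSeries(times=times, values=values, period=1.0)


class TestProperties:
    @given(random_series(), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling(self, s, c):
        scaled = WSSTimeSeries(s.times, c * s.values, s.period)
        assert np.allclose(tawss(scaled), c * tawss(s))
        assert np.allclose(osi(scaled), osi(s), atol=1e-12)
        t, o = tawss(s), osi(s)
        nz = t > 1e-6
        assert np.allclose(
            ecap(tawss(scaled), osi(scaled))[nz], ecap(t, o)[nz] / c, rtol=1e-6
        )

    @given(random_series())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rotation_invariance(self, s):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [0.5, 1.0, -0.3]).as_matrix()
        rot = WSSTimeSeries(s.times, s.values @ R.T, s.period)
        assert np.allclose(tawss(rot), tawss(s))
        assert np.allclose(osi(rot), osi(s), atol=1e-12)

    @given(random_series())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_osi_bounds(self, s):
        o = osi(s)
        assert np.all(o >= 0) and np.all(o <= 0.5)
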