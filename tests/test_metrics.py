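import numpy as np
import pandas as pd
import pytest

from laaecap.metrics import (
    ExperimentPlan,
    kfold_assignments,
    mae,
    run_kfold,
    run_sequential,
    summarize,
    tpr_at_percentile,
)
from laaecap.synthetic import Case


class TestMae:
    def test_perfect_prediction(self):
        g = [np.arange(5.0)]
        assert mae(g, g) == 0.0

    def test_constant_offset(self):
        g = [np.arange(5.0), np.arange(3.0)]
        p = [x + 0.5 for x in g]
        assert np.isclose(mae(p, g), 0.5)

    def test_vertex_pooled_weighting(self):
        g = [np.zeros(10), np.zeros(30)]
        p = [np.full(10, 0.2), np.full(30, 0.4)]
        assert np.isclose(mae(p, g), 0.35)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([np.zeros(3)], [np.zeros(4)])

    def test_invariant_to_ordering_and_permutation(self):
        rng = np.random.default_rng(0)
        g = [rng.random(20), rng.random(15)]
        p = [rng.random(20), rng.random(15)]
        m0 = mae(p, g)
        perm = rng.permutation(20)
        assert np.isclose(mae([p[1], p[0][perm]], [g[1], g[0][perm]]), m0)


class TestTpr:
    def test_perfect_prediction_100(self):
        g = [np.arange(100.0)]
        t, tau = tpr_at_percentile(g, g, 90)
        assert t == 100.0

    def test_constant_min_prediction_0(self):
        g = [np.arange(100.0)]
        p = [np.zeros(100)]
        assert tpr_at_percentile(p, g, 90)[0] == 0.0

    def test_hand_confusion_example(self):
        # 21 values: the interpolated 90th percentile sits at the 19th
        # order statistic, leaving exactly 2 positives; recover 1 -> 50%
        g = [np.arange(21.0)]
        tau = np.percentile(g[0], 90)
        assert np.sum(g[0] > tau) == 2
        p = g[0].copy()
        p[20] = tau - 1  # miss the largest positive
        assert tpr_at_percentile([p], g, 90)[0] == 50.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        g = [rng.random(200)]
        p = [rng.random(200)]
        t0, _ = tpr_at_percentile(p, g, 90)
        t1, _ = tpr_at_percentile([np.expm1(p[0])], [np.expm1(g[0])], 90)
        assert t0 == t1

    def test_degenerate_threshold_rejected(self):
        g = [np.ones(10)]
        with pytest.raises(ValueError):
            tpr_at_percentile(g, g, 90)


class TestFolds:
    def test_even_disjoint_cover(self):
        ids = [f"c{i}" for i in range(16)]
        folds = kfold_assignments(ids, 8, seed=0)
        assert all(len(f) == 2 for f in folds)
        flat = np.concatenate(folds)
        assert sorted(flat) == sorted(ids)

    def test_deterministic(self):
        ids = [f"c{i}" for i in range(10)]
        a = kfold_assignments(ids, 3, seed=4)
        b = kfold_assignments(ids, 3, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_assignments(["a", "b"], 3, seed=0)


class _MeanAdapter:
    """Predicts the training-mean constant field (topology-agnostic)."""

    name = "mean"

    def fit(self, train, val, seed):
        self.mu = float(np.mean(np.concatenate([c.ecap for c in train])))
        self.train_ids = {c.case_id for c in train} | {c.case_id for c in val}

    def predict(self, case):
        return np.full(case.mesh.n_vertices, self.mu)


def toy_cases(n=12, V=30, seed=0):
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        mesh = type("M", (), {"n_vertices": V})()
        ecap = rng.random(V) + 0.05 * i
        hemo = type("H", (), {"ecap": ecap})()
        cases.append(Case(case_id=f"case{i}", mesh=mesh, dist=None, hemo=hemo))
    return cases


class TestProtocols:
    def test_kfold_no_train_test_overlap(self):
        cases = toy_cases()
        plan = ExperimentPlan(
            dataset_ids=[c.case_id for c in cases], k=4, seeds=[0], arch="mean"
        )
        seen = {}

        class CheckAdapter(_MeanAdapter):
            def predict(self, case):
                assert case.case_id not in self.train_ids
                return super().predict(case)

        df = run_kfold(plan, cases, CheckAdapter)
        assert len(df) == 4
        assert df["n_test"].sum() == len(cases)

    def test_kfold_deterministic(self):
        cases = toy_cases()
        plan = ExperimentPlan(
            dataset_ids=[c.case_id for c in cases], k=3, seeds=[1], arch="mean"
        )
        a = run_kfold(plan, cases, _MeanAdapter)
        b = run_kfold(plan, cases, _MeanAdapter)
        pd.testing.assert_frame_equal(a, b)

    def test_sequential_nested_subsets(self):
        cases = toy_cases(20)
        plan = ExperimentPlan(
            dataset_ids=[c.case_id for c in cases],
            protocol="sequential",
            k=4,
            sizes=[4, 8, 12],
            seeds=[0],
            arch="mean",
        )
        subsets = []

        class RecordingAdapter(_MeanAdapter):
            def fit(self, train, val, seed):
                super().fit(train, val, seed)
                subsets.append(self.train_ids)

        run_sequential(plan, cases, RecordingAdapter)
        assert subsets[0] <= subsets[1] <= subsets[2]

    def test_sequential_baseline_always_included(self):
        cases = toy_cases(20)
        baseline = ["case0", "case1"]
        plan = ExperimentPlan(
            dataset_ids=[c.case_id for c in cases],
            protocol="sequential",
            k=4,
            sizes=[3, 6],
            seeds=[0],
            arch="mean",
            baseline_ids=baseline,
        )

        class CheckAdapter(_MeanAdapter):
            def fit(self, train, val, seed):
                super().fit(train, val, seed)
                assert set(baseline) <= self.train_ids

        run_sequential(plan, cases, CheckAdapter)

    def test_ladder_exceeding_pool_rejected(self):
        cases = toy_cases(8)
        plan = ExperimentPlan(
            dataset_ids=[c.case_id for c in cases],
            protocol="sequential",
            k=4,
            sizes=[10],
            seeds=[0],
            arch="mean",
        )
        with pytest.raises(ValueError):
            run_sequential(plan, cases, _MeanAdapter)


class TestSummarize:
    def test_single_row_sd_zero(self):
        df = pd.DataFrame(
            [dict(arch="a", protocol="kfold", condition="fold0", seed=0, mae=0.5, tpr=80.0)]
        )
        agg = summarize(df)
        assert agg.loc[0, "mae_sd"] == 0.0

    def test_two_row_mean(self):
        df = pd.DataFrame(
            [
                dict(arch="a", protocol="kfold", condition="fold0", seed=s, mae=m, tpr=70.0)
                for s, m in [(0, 0.5), (1, 0.7)]
            ]
        )
        agg = summarize(df)
        assert np.isclose(agg.loc[0, "mae_mean"], 0.6)

    def test_schema(self, tmp_path):
        df = pd.DataFrame(
            [dict(arch="a", protocol="kfold", condition="fold0", seed=0, mae=0.1, tpr=50.0)]
        )
        out = str(tmp_path / "agg.csv")
        agg = summarize(df, out)
        assert list(agg.columns) == [
            "arch",
            "protocol",
            "condition",
            "mae_mean",
            "mae_sd",
            "tpr_mean",
            "tpr_sd",
            "n_runs",
        ]
        assert (tmp_path / "agg.csv").exists()
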