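"""Evaluation metrics and experiment protocols.

Accuracy is reported as the vertex-pooled mean absolute error of the
predicted ECAP and as the true-positive rate of the binary
"pro-thrombotic" classification, which thresholds both ground truth and
prediction at the 90th percentile of the pooled ground-truth
distribution.  Two experiment drivers are provided:
k-fold cross-validation (optionally per cohort) and sequential
training-size scaling with nested subsets and a fixed test fold, with
10% of each training set held out for best-checkpoint selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .synthetic import Case

__all__ = [
    "mae",
    "tpr_at_percentile",
    "ExperimentPlan",
    "SurrogateAdapter",
    "run_kfold",
    "run_sequential",
    "summarize",
]


def mae(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray]) -> float:
    """Vertex-pooled mean absolute error across all test cases."""
    if len(preds) != len(gts):
        raise ValueError("prediction/ground-truth case counts differ")
    num, den = 0.0, 0
    for p, g in zip(preds, gts):
        p, g = np.asarray(p), np.asarray(g)
        if p.shape != g.shape:
            raise ValueError("per-case shape mismatch")
        num += float(np.abs(p - g).sum())
        den += p.size
    return num / den


def tpr_at_percentile(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    percentile: float = 90.0,
) -> tuple[float, float]:
    """Pooled true-positive rate (%) at the ground-truth percentile
    threshold; returns (tpr_percent, threshold)."""
    gt_all = np.concatenate([np.asarray(g).ravel() for g in gts])
    pred_all = np.concatenate([np.asarray(p).ravel() for p in preds])
    tau = float(np.percentile(gt_all, percentile))  # linear interpolation
    pos = gt_all > tau
    if not np.any(pos):
        raise ValueError("degenerate threshold: no positive vertices")
    tp = np.sum(pos & (pred_all > tau))
    return 100.0 * tp / pos.sum(), tau


class SurrogateAdapter(Protocol):
    """Uniform training/prediction interface over the architectures."""

    name: str

    def fit(self, train: list[Case], val: list[Case], seed: int) -> None: ...

    def predict(self, case: Case) -> np.ndarray: ...


@dataclass
class ExperimentPlan:
    dataset_ids: list[str]
    protocol: str = "kfold"  # or "sequential"
    k: int = 6
    sizes: list[int] = dc_field(default_factory=list)
    seeds: list[int] = dc_field(default_factory=lambda: [0, 1, 2])
    val_fraction: float = 0.10
    arch: str = "geometric"
    percentile: float = 90.0
    baseline_ids: list[str] = dc_field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.protocol == "sequential":
            if not self.sizes:
                raise ValueError("sequential protocol requires a size ladder")
            if np.any(np.diff(self.sizes) <= 0):
                raise ValueError("sizes must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentPlan":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _split_val(train_ids: np.ndarray, val_fraction: float, rng: np.random.Generator):
    n_val = max(1, int(round(val_fraction * len(train_ids))))
    perm = rng.permutation(len(train_ids))
    return train_ids[perm[n_val:]], train_ids[perm[:n_val]]


def _select(cases: dict[str, Case], ids) -> list[Case]:
    return [cases[i] for i in ids]


def _evaluate(adapter: SurrogateAdapter, test: list[Case], percentile: float):
    preds = [adapter.predict(c) for c in test]
    gts = [c.ecap for c in test]
    m = mae(preds, gts)
    t, tau = tpr_at_percentile(preds, gts, percentile)
    return m, t, tau


def kfold_assignments(ids: list[str], k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, folds as equal as possible, partitioning `ids`."""
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available cases")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [np.array(ids, dtype=object)[p] for p in np.array_split(perm, k)]


def run_kfold(
    plan: ExperimentPlan,
    cases: list[Case],
    adapter_factory: Callable[[], SurrogateAdapter],
) -> pd.DataFrame:
    by_id = {c.case_id: c for c in cases}
    rows = []
    for seed in plan.seeds:
        folds = kfold_assignments(plan.dataset_ids, plan.k, seed)
        for fi, test_ids in enumerate(folds):
            train_ids = np.array(
                [i for i in plan.dataset_ids if i not in set(test_ids)], dtype=object
            )
            tr, va = _split_val(train_ids, plan.val_fraction, np.random.default_rng(seed + 1000 * fi))
            adapter = adapter_factory()
            adapter.fit(_select(by_id, tr), _select(by_id, va), seed)
            m, t, tau = _evaluate(adapter, _select(by_id, test_ids), plan.percentile)
            rows.append(
                dict(
                    arch=plan.arch,
                    protocol="kfold",
                    condition=f"fold{fi}",
                    seed=seed,
                    mae=m,
                    tpr=t,
                    threshold=tau,
                    n_train=len(tr),
                    n_test=len(test_ids),
                )
            )
    return pd.DataFrame(rows)


def run_sequential(
    plan: ExperimentPlan,
    cases: list[Case],
    adapter_factory: Callable[[], SurrogateAdapter],
) -> pd.DataFrame:
    """Nested training subsets over the size ladder with a fixed test
    fold; an optional baseline cohort is always part of training."""
    by_id = {c.case_id: c for c in cases}
    rows = []
    for seed in plan.seeds:
        folds = kfold_assignments(plan.dataset_ids, plan.k, seed)
        test_ids = folds[0]
        pool = [
            i
            for i in plan.dataset_ids
            if i not in set(test_ids) and i not in set(plan.baseline_ids)
        ]
        if max(plan.sizes) > len(pool):
            raise ValueError(
                f"size ladder {plan.sizes} exceeds the {len(pool)}-case pool"
            )
        order = np.random.default_rng(seed).permutation(len(pool))
        for size in plan.sizes:
            subset = [pool[i] for i in order[:size]] + list(plan.baseline_ids)
            tr, va = _split_val(
                np.array(subset, dtype=object), plan.val_fraction,
                np.random.default_rng(seed + 7919),
            )
            adapter = adapter_factory()
            adapter.fit(_select(by_id, tr), _select(by_id, va), seed)
            m, t, tau = _evaluate(adapter, _select(by_id, test_ids), plan.percentile)
            rows.append(
                dict(
                    arch=plan.arch,
                    protocol="sequential",
                    condition=f"n{size}",
                    seed=seed,
                    mae=m,
                    tpr=t,
                    threshold=tau,
                    n_train=len(tr),
                    n_test=len(test_ids),
                )
            )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, csv_path: str | None = None) -> pd.DataFrame:
    """Mean +/- sd of MAE and TPR per (arch, protocol, condition)."""
    if len(results) == 0:
        raise ValueError("empty result table")
    agg = (
        results.groupby(["arch", "protocol", "condition"])
        .agg(
            mae_mean=("mae", "mean"),
            mae_sd=("mae", lambda x: float(np.std(x, ddof=0)) if len(x) > 1 else 0.0),
            tpr_mean=("tpr", "mean"),
            tpr_sd=("tpr", lambda x: float(np.std(x, ddof=0)) if len(x) > 1 else 0.0),
            n_runs=("mae", "size"),
        )
        .reset_index()
    )
    if csv_path:
        agg.to_csv(csv_path, index=False)
    return agg
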