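"""Repeated-split evaluation, platform comparison, frozen-model application.

Prediction performance is summarised over repeated random 70/30 stratified
splits (default 100), each with a fresh cross-validated L1 fit, to average
out split-to-split variability. Platform degradation re-runs the same
evaluation on the probe subsets present on successive array generations
(EPICv2 > EPICv1 > Methyl450K > Methyl27K) and compares the per-iteration
metric distributions pairwise. ``apply_model`` applies a frozen classifier
to a new cohort and reports the predicted carriers.

Error-rate conventions: type I = FP / (FP + TN) among true non-carriers,
type II = FN / (FN + TP) among true carriers (NaN when a test split holds
no carriers, which only happens in unstratified mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PLATFORMS
from .datasets import CARRIER, MethylationDataset
from .predictor import (
    PredictorModel,
    predict_carriers,
    select_locus_probes,
    split_train_test,
    train_lasso,
)

__all__ = [
    "SplitMetrics",
    "EvaluationResult",
    "PlatformComparison",
    "CarrierCalls",
    "repeated_evaluation",
    "platform_degradation",
    "apply_model",
]


@dataclass(frozen=True)
class SplitMetrics:
    """Confusion counts of one test split, with derived error rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "SplitMetrics":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def type1(self) -> float:
        """False-positive rate among true non-carriers."""
        denom = self.fp + self.tn
        return self.fp / denom if denom else float("nan")

    @property
    def type2(self) -> float:
        """False-negative rate among true carriers."""
        denom = self.fn + self.tp
        return self.fn / denom if denom else float("nan")


@dataclass
class EvaluationResult:
    """Per-iteration metrics of a repeated-split evaluation."""

    platform: str
    n_iterations: int
    metrics: list[SplitMetrics]
    seeds: list[int]
    n_probes: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.metrics) != self.n_iterations:
            raise ValueError("metrics length must equal n_iterations")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": i,
                "seed": s,
                "tp": m.tp,
                "fp": m.fp,
                "tn": m.tn,
                "fn": m.fn,
                "accuracy": m.accuracy,
                "type1": m.type1,
                "type2": m.type2,
            }
            for i, (m, s) in enumerate(zip(self.metrics, self.seeds))
        ]
        return pd.DataFrame(rows)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics])

    def summary(self) -> dict:
        """Mean and SD of accuracy and error rates across iterations."""
        out = {"platform": self.platform, "n_iterations": self.n_iterations}
        for name in ("accuracy", "type1", "type2"):
            vals = self.metric_values(name)
            out[f"{name}_mean"] = float(np.nanmean(vals))
            out[f"{name}_sd"] = float(np.nanstd(vals, ddof=1))
        return out


def repeated_evaluation(
    ds: MethylationDataset,
    probes: list[str],
    n_iterations: int = 100,
    root_seed: int = 0,
    train_fraction: float = 0.7,
    cv_folds: int = 10,
    threshold: float = 0.5,
    stratified: bool = True,
    platform: str = "custom",
) -> EvaluationResult:
    """Evaluate the locus classifier over repeated random splits.

    Each iteration draws a fresh stratified 70/30 split (seed =
    ``root_seed + iteration`` for auditability), trains the cross-validated
    L1 model on the training part and scores the held-out part. An error in
    any iteration aborts with its index and seed.
    """
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    metrics: list[SplitMetrics] = []
    seeds: list[int] = []
    for i in range(n_iterations):
        seed = root_seed + i
        try:
            train, test = split_train_test(
                ds, train_fraction=train_fraction, seed=seed, stratified=stratified
            )
            model = train_lasso(train, probes, cv_folds=cv_folds, seed=seed)
            calls = predict_carriers(model, test, threshold=threshold)
        except Exception as err:
            raise RuntimeError(
                f"evaluation iteration {i} (seed {seed}) failed: {err}"
            ) from err
        y_true = test.carrier_mask()
        y_pred = (calls["label"] == CARRIER).to_numpy()
        metrics.append(SplitMetrics.from_labels(y_true, y_pred))
        seeds.append(seed)
    return EvaluationResult(
        platform=platform,
        n_iterations=n_iterations,
        metrics=metrics,
        seeds=seeds,
        n_probes=len(probes),
        metadata={
            "train_fraction": train_fraction,
            "cv_folds": cv_folds,
            "threshold": threshold,
            "stratified": stratified,
            "root_seed": root_seed,
        },
    )


@dataclass
class PlatformComparison:
    """Pairwise tests comparing per-iteration metric distributions."""

    table: pd.DataFrame  # platform_a, platform_b, metric, statistic, p
    test: str

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<PlatformComparison test={self.test}, {len(self.table)} rows>"


def platform_degradation(
    ds: MethylationDataset,
    annotation: pd.DataFrame,
    n_iterations: int = 100,
    root_seed: int = 0,
    platforms: tuple[str, ...] = PLATFORMS,
    paired_seeds: bool = True,
    test: str = "welch",
    **eval_kwargs,
) -> tuple[dict[str, EvaluationResult], PlatformComparison]:
    """Repeat the evaluation on each platform's locus probe subset.

    With ``paired_seeds`` (default) every platform sees the same split
    sequence, so platform differences are not confounded with split noise.
    Metric distributions are compared pairwise with a two-sided Welch
    t-test (``test="ranksum"`` switches to Mann-Whitney U).
    """
    if test not in ("welch", "ranksum"):
        raise ValueError("test must be 'welch' or 'ranksum'")
    results: dict[str, EvaluationResult] = {}
    for k, platform in enumerate(platforms):
        try:
            probes = select_locus_probes(annotation, platform=platform)
        except ValueError:
            warnings.warn(f"platform {platform!r} has no locus probes; skipped")
            continue
        probes = [p for p in probes if p in ds.m_values.columns]
        if not probes:
            warnings.warn(f"platform {platform!r} probes absent from data; skipped")
            continue
        seed = root_seed if paired_seeds else root_seed + 100_000 * k
        results[platform] = repeated_evaluation(
            ds,
            probes,
            n_iterations=n_iterations,
            root_seed=seed,
            platform=platform,
            **eval_kwargs,
        )
    rows = []
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for metric in ("accuracy", "type1", "type2"):
                va = results[a].metric_values(metric)
                vb = results[b].metric_values(metric)
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                if np.array_equal(va, vb):
                    stat, p = 0.0, 1.0
                elif test == "welch":
                    stat, p = stats.ttest_ind(va, vb, equal_var=False)
                else:
                    stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
                rows.append(
                    {
                        "platform_a": a,
                        "platform_b": b,
                        "metric": metric,
                        "statistic": float(stat),
                        "p": max(float(p), np.finfo(float).tiny),
                    }
                )
    comparison = PlatformComparison(table=pd.DataFrame(rows), test=test)
    return results, comparison


@dataclass
class CarrierCalls:
    """Frozen-model predictions on a cohort."""

    calls: pd.DataFrame  # per-sample probability and label
    carrier_ids: list[str]
    prevalence: float  #: predicted carriers / cohort size

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)

    def summary(self) -> str:
        return (
            f"{self.n_carriers} predicted carriers among {len(self.calls)} "
            f"samples (prevalence {100 * self.prevalence:.2f}%): "
            f"{', '.join(self.carrier_ids) or '-'}"
        )


def apply_model(
    model: PredictorModel, ds: MethylationDataset, threshold: float = 0.5
) -> CarrierCalls:
    """Apply a frozen classifier to an independent cohort.

    Every model probe must be present with complete values (no silent
    imputation). Returns per-sample probabilities plus the predicted
    carrier list and cohort prevalence.
    """
    if ds.n_samples == 0:
        raise ValueError("dataset is empty")
    calls = predict_carriers(model, ds, threshold=threshold)
    carrier_ids = calls.index[calls["label"] == CARRIER].tolist()
    return CarrierCalls(
        calls=calls,
        carrier_ids=carrier_ids,
        prevalence=len(carrier_ids) / len(calls),
    )
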