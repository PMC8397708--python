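"""Chromothripsis prediction from signature exposures.

A stratified k-fold cross-validated L2-regularized logistic regression on
exposure fractions produces out-of-fold chromothripsis probabilities; the
reported AUC is the mean of per-fold AUCs (the pooled out-of-fold AUC is
kept alongside).  The binary CN_pred call labels a sample high when its
probability is >= 0.6, the level that keeps specificity at or above 95%
while maximizing sensitivity on the cohorts this framework targets.

Two exposure sets are compared by the bootstrap: the point difference in
mean CV AUC on the full data, and its standard deviation over bootstrap
resamples of the cohort (each replicate re-runs the full k-fold CV for
both feature sets), with a two-sided normal-approximation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PredictionResult",
    "AucComparison",
    "crossval_predict",
    "roc_auc",
    "compare_auc_bootstrap",
    "call_cn_pred",
    "threshold_sweep",
    "audit_discrepancies",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6


@dataclass
class PredictionResult:
    sample_ids: list[str]
    probabilities: np.ndarray      # out-of-fold, in sample order
    folds: np.ndarray              # test-fold index per sample
    fold_aucs: list[float]
    mean_auc: float
    pooled_auc: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "probability": self.probabilities,
                "fold": self.folds,
            }
        ).set_index("sample")


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    bootstrap_sd: float
    p_value: float
    n_boot: int
    n_redrawn: int = 0


def _as_xy(exposures: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(pd.Series(labels).reindex(exposures.index) if isinstance(labels, (pd.Series, dict)) else labels)
    y = y.astype(int)
    x = exposures.to_numpy(dtype=float)
    if len(y) != len(x):
        raise ValueError("labels and exposures length mismatch")
    return x, y


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC with midrank tie handling."""
    return float(roc_auc_score(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)))


def crossval_predict(
    exposures: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> PredictionResult:
    """Stratified k-fold CV logistic prediction of the binary label.

    All signatures enter the model as features.  Requires both classes
    present and k no larger than the minority-class count.
    """
    x, y = _as_xy(exposures, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of samples ({len(y)})")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority-class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    probs = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    fold_aucs: list[float] = []
    curves = []
    for fold, (train, test) in enumerate(skf.split(x, y)):
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        model.fit(x[train], y[train])
        p = model.predict_proba(x[test])[:, 1]
        probs[test] = p
        folds[test] = fold
        fold_aucs.append(roc_auc(p, y[test]))
        fpr, tpr, _ = roc_curve(y[test], p)
        curves.append((fpr, tpr))
    return PredictionResult(
        sample_ids=[str(s) for s in exposures.index],
        probabilities=probs,
        folds=folds,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        pooled_auc=roc_auc(probs, y),
        roc_curves=curves,
    )


def _cv_mean_auc(x: np.ndarray, y: np.ndarray, k: int, seed: int, C: float) -> float:
    k_eff = int(min(k, np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(x, y):
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        model.fit(x[train], y[train])
        aucs.append(roc_auc(model.predict_proba(x[test])[:, 1], y[test]))
    return float(np.mean(aucs))


def compare_auc_bootstrap(
    exposures_a: pd.DataFrame,
    exposures_b: pd.DataFrame,
    labels,
    k: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    max_redraws: int = 1000,
) -> AucComparison:
    """Bootstrap comparison of two feature sets' mean CV AUC on one cohort.

    Replicates resample the cohort with replacement; a replicate leaving a
    single class (or fewer than 2 minority samples) is redrawn and logged.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for a bootstrap SD")
    if list(exposures_a.index) != list(exposures_b.index):
        raise ValueError("feature sets must cover the same samples in the same order")
    xa, y = _as_xy(exposures_a, labels)
    xb, _ = _as_xy(exposures_b, labels)
    auc_a = _cv_mean_auc(xa, y, k, seed, C)
    auc_b = _cv_mean_auc(xb, y, k, seed, C)
    diff = auc_a - auc_b
    rng = np.random.default_rng(seed)
    diffs = []
    n_redrawn = 0
    n = len(y)
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        counts = np.bincount(yb, minlength=2)
        if counts.min() < 2:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            logger.info("bootstrap replicate redrawn (single-class resample)")
            continue
        rep_seed = int(rng.integers(0, 2**31 - 1))
        da = _cv_mean_auc(xa[idx], yb, k, rep_seed, C)
        db = _cv_mean_auc(xb[idx], yb, k, rep_seed, C)
        diffs.append(da - db)
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(2.0 * (1.0 - stats.norm.cdf(abs(diff) / sd)))
    return AucComparison(
        auc_a=auc_a, auc_b=auc_b, difference=float(diff),
        bootstrap_sd=sd, p_value=p, n_boot=n_boot, n_redrawn=n_redrawn,
    )


def call_cn_pred(
    result: PredictionResult,
    labels=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Binarize out-of-fold probabilities into high/low CN_pred calls.

    A probability exactly at the threshold is called high.  With labels
    given, sensitivity/specificity and the confusion counts are attached as
    DataFrame attrs.
    """
    high = result.probabilities >= threshold
    calls = pd.DataFrame(
        {
            "sample": result.sample_ids,
            "probability": result.probabilities,
            "cn_pred": np.where(high, "high", "low"),
        }
    ).set_index("sample")
    if labels is not None:
        y = np.asarray(labels, dtype=int)
        tp = int((high & (y == 1)).sum())
        fn = int((~high & (y == 1)).sum())
        tn = int((~high & (y == 0)).sum())
        fp = int((high & (y == 0)).sum())
        calls.attrs["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        calls.attrs["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        calls.attrs["confusion"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return calls


def threshold_sweep(result: PredictionResult, labels) -> pd.DataFrame:
    """Sensitivity/specificity at every observed probability threshold."""
    y = np.asarray(labels, dtype=int)
    rows = []
    for thr in np.unique(result.probabilities):
        high = result.probabilities >= thr
        tp = (high & (y == 1)).sum()
        fn = (~high & (y == 1)).sum()
        tn = (~high & (y == 0)).sum()
        fp = (high & (y == 0)).sum()
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def select_threshold(sweep: pd.DataFrame, min_specificity: float = 0.95) -> float:
    """Smallest threshold whose specificity is at/above ``min_specificity``
    (maximizes sensitivity under the specificity constraint)."""
    ok = sweep[sweep["specificity"] >= min_specificity]
    if ok.empty:
        return float(sweep["threshold"].max())
    return float(ok["threshold"].min())


def audit_discrepancies(
    result: PredictionResult,
    labels,
    event_calls: pd.DataFrame | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """List false-positive / false-negative samples; with an event-call
    table attached, report each discrepant sample's complex-NOS and other
    event content (complex-but-subthreshold patterns often explain FPs)."""
    y = np.asarray(labels, dtype=int)
    high = result.probabilities >= threshold
    rows = []
    for i, sample in enumerate(result.sample_ids):
        if bool(high[i]) == bool(y[i]):
            continue
        row = {
            "sample": sample,
            "kind": "false_positive" if high[i] else "false_negative",
            "probability": float(result.probabilities[i]),
        }
        if event_calls is not None and len(event_calls):
            sub = event_calls[event_calls["sample"] == sample]
            row["n_complex_nos"] = int((sub["class"] == "complex_nos").sum())
            row["classes"] = ",".join(sorted(sub["class"].unique()))
        rows.append(row)
    return pd.DataFrame(rows)
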