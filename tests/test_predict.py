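"""Cross-validated prediction, AUC, bootstrap comparison and CN_pred calls."""

import numpy as np
import pandas as pd
import pytest

from cnsig.predict import (
    PredictionResult,
    audit_discrepancies,
    call_cn_pred,
    compare_auc_bootstrap,
    crossval_predict,
    roc_auc,
    select_threshold,
    threshold_sweep,
)

from oracles import auc_brute


def separable_exposures(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 3] = 1
    x = np.zeros((n, 3))
    x[:, 0] = np.where(y == 1, 0.9, 0.0) + rng.uniform(0, 0.02, n)
    x[:, 1] = rng.uniform(0, 0.05, n)
    x[:, 2] = 1 - x[:, 0] - x[:, 1]
    return pd.DataFrame(x, index=[f"S{i}" for i in range(n)], columns=list("abc")), y


def test_roc_auc_examples():
    assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


@pytest.mark.parametrize("seed", range(5))
def test_roc_auc_matches_pair_counting(seed):
    rng = np.random.default_rng(seed)
    scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=40)
    labels = rng.integers(0, 2, 40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(auc_brute(scores, labels))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    assert roc_auc(scores, labels) == pytest.approx(roc_auc(np.exp(3 * scores), labels))


def test_separable_exposures_auc_one():
    x, y = separable_exposures()
    res = crossval_predict(x, y, k=10, seed=0)
    assert res.mean_auc == 1.0
    assert res.pooled_auc == 1.0


def test_each_sample_in_exactly_one_test_fold():
    x, y = separable_exposures()
    res = crossval_predict(x, y, k=5, seed=0)
    assert len(res.folds) == len(y)
    assert set(res.folds) == set(range(5))


def test_permuted_labels_auc_near_half():
    x, y = separable_exposures(n=100, seed=1)
    rng = np.random.default_rng(3)
    aucs = []
    for _ in range(30):
        res = crossval_predict(x, rng.permutation(y), k=5, seed=0)
        aucs.append(res.mean_auc)
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_duplicated_cohort_same_auc():
    x, y = separable_exposures(n=40, seed=4)
    res1 = crossval_predict(x, y, k=5, seed=0)
    x2 = pd.concat([x, x.set_index(x.index + "_dup")])
    y2 = np.concatenate([y, y])
    res2 = crossval_predict(x2, y2, k=5, seed=0)
    assert res2.mean_auc == pytest.approx(res1.mean_auc, abs=0.02)


def test_single_class_and_bad_k_rejected():
    x, y = separable_exposures(n=30)
    with pytest.raises(ValueError, match="single class"):
        crossval_predict(x, np.zeros(30, dtype=int), k=5)
    with pytest.raises(ValueError, match="minority"):
        crossval_predict(x, y, k=11)
    with pytest.raises(ValueError, match="exceeds the number"):
        crossval_predict(x, y, k=31)


# ---------------------------------------------------------------------------
# CN_pred threshold semantics


def _result(probs):
    probs = np.asarray(probs, dtype=float)
    return PredictionResult(
        sample_ids=[f"S{i}" for i in range(len(probs))],
        probabilities=probs,
        folds=np.zeros(len(probs), dtype=int),
        fold_aucs=[1.0],
        mean_auc=1.0,
        pooled_auc=1.0,
    )


def test_probability_exactly_at_threshold_is_high():
    calls = call_cn_pred(_result([0.6, 0.59999, 0.61]))
    assert list(calls["cn_pred"]) == ["high", "low", "high"]


def test_all_zero_probabilities_all_low_full_specificity():
    calls = call_cn_pred(_result([0.0, 0.0, 0.0]), labels=[0, 0, 1])
    assert set(calls["cn_pred"]) == {"low"}
    assert calls.attrs["specificity"] == 1.0
    assert calls.attrs["sensitivity"] == 0.0


def test_threshold_sweep_monotone_and_selection():
    x, y = separable_exposures(n=80, seed=5)
    res = crossval_predict(x, y, k=5, seed=0)
    sweep = threshold_sweep(res, y)
    s = sweep.sort_values("threshold")
    assert (np.diff(s["sensitivity"]) <= 1e-12).all()
    assert (np.diff(s["specificity"]) >= -1e-12).all()
    thr = select_threshold(sweep, min_specificity=0.95)
    sel = sweep[sweep["threshold"] == thr].iloc[0]
    assert sel["specificity"] >= 0.95


def test_audit_lists_discrepant_samples():
    res = _result([0.9, 0.1, 0.7])
    y = [0, 1, 1]
    events = pd.DataFrame({"sample": ["S0", "S0"], "class": ["complex_nos", "single"]})
    audit = audit_discrepancies(res, y, events)
    kinds = dict(zip(audit["sample"], audit["kind"]))
    assert kinds == {"S0": "false_positive", "S1": "false_negative"}
    assert audit.set_index("sample").loc["S0", "n_complex_nos"] == 1


# ---------------------------------------------------------------------------
# bootstrap comparison


def test_identical_feature_sets_zero_difference():
    x, y = separable_exposures(n=60, seed=6)
    cmp = compare_auc_bootstrap(x, x, y, k=5, n_boot=10, seed=0)
    assert cmp.difference == 0.0
    assert cmp.p_value > 0.9


def test_informative_vs_noise_significant():
    x, y = separable_exposures(n=120, seed=7)
    rng = np.random.default_rng(8)
    noise = pd.DataFrame(rng.random((120, 3)), index=x.index, columns=list("xyz"))
    cmp = compare_auc_bootstrap(x, noise, y, k=5, n_boot=40, seed=0)
    assert cmp.difference > 0.3
    assert cmp.p_value < 0.05
    assert cmp.bootstrap_sd > 0


def test_single_replicate_bootstrap_rejected():
    x, y = separable_exposures(n=30)
    with pytest.raises(ValueError, match="n_boot"):
        compare_auc_bootstrap(x, x, y, n_boot=1)
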