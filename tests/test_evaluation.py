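"""Blind-set rule, CV partition, metrics, ROC, and stepwise regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breathprint.evaluation import (
    assign_blind_set,
    classify,
    confusion_metrics,
    diagnostic_report,
    leave_10pct_out_cv,
    leave_10pct_out_folds,
    logistic_stepwise,
    report_from_counts,
    roc_points_auc,
    round_half_up,
)
from breathprint.io import N_CYCLE, N_SENSOR, N_TEMP, SensorTensor


def tensor_sequence(labels):
    """Minimal cohort with the given label sequence in measurement order."""
    base = np.zeros((N_TEMP, N_CYCLE, N_SENSOR))
    base[0, 0, 0] = 1.0  # non-constant
    return [
        SensorTensor(f"p{i}", base, order_index=i, label=lab)
        for i, lab in enumerate(labels)
    ]


# ---------------------------------------------------------------------------
# block-size blind-set rule


def test_sixth_consecutive_case_is_blinded():
    cohort = tensor_sequence(["positive"] * 6)
    training, blinded = assign_blind_set(cohort)
    assert [t.participant_id for t in training] == [f"p{i}" for i in range(5)]
    assert [t.participant_id for t in blinded] == ["p5"]


def test_alternating_labels_give_empty_blind_set():
    cohort = tensor_sequence(["positive", "negative"] * 6)
    training, blinded = assign_blind_set(cohort)
    assert blinded == []
    assert len(training) == 12


def test_hand_traced_partition_with_reset():
    # 7 cases, 1 control, 6 cases: participants 6, 7 and 14 (1-indexed) blinded
    labels = ["positive"] * 7 + ["negative"] + ["positive"] * 6
    cohort = tensor_sequence(labels)
    _, blinded = assign_blind_set(cohort)
    assert [t.order_index for t in blinded] == [5, 6, 13]


def test_blind_rule_uses_order_index_not_list_order():
    labels = ["positive"] * 6
    cohort = tensor_sequence(labels)
    shuffled = [cohort[i] for i in (3, 0, 5, 1, 4, 2)]
    _, blinded = assign_blind_set(shuffled)
    assert [t.order_index for t in blinded] == [5]


def test_blind_rule_rejects_duplicate_order_index():
    cohort = tensor_sequence(["positive"] * 3)
    cohort[2].order_index = 0
    with pytest.raises(ValueError, match="order_index"):
        assign_blind_set(cohort)


# ---------------------------------------------------------------------------
# Leave-10%-Out partition


def test_fold_arithmetic_n30():
    y = np.array([0, 1] * 15)
    folds = leave_10pct_out_folds(y, seed=4)
    sizes = np.bincount(folds)
    assert len(sizes) == 10
    assert np.all(sizes == 3)


def test_fold_arithmetic_n84():
    y = np.array([1] * 49 + [0] * 35)
    folds = leave_10pct_out_folds(y, seed=0)
    sizes = np.bincount(folds)
    assert len(sizes) == 10
    assert sorted(sizes.tolist()) == [3] + [9] * 9
    assert sizes[-1] == 3  # the final fold is the small one


def test_folds_partition_everyone_exactly_once():
    y = np.array([0, 1] * 21)
    folds = leave_10pct_out_folds(y, seed=9)
    assert folds.shape == (42,)
    assert set(np.unique(folds)) == set(range(folds.max() + 1))


def test_cv_rejects_tiny_cohorts():
    with pytest.raises(ValueError, match=">= 10"):
        leave_10pct_out_folds(np.array([0, 1] * 4))


def test_stratification_balances_folds():
    y = np.array([1] * 40 + [0] * 40)
    folds = leave_10pct_out_folds(y, seed=2)
    for f in range(folds.max() + 1):
        in_fold = y[folds == f]
        assert 0 < in_fold.mean() < 1  # both classes in every full fold


class _RecordingStub:
    """Estimator stub proving the no-leakage contract: records the rows it
    was trained on and predicts their count."""

    def __init__(self, random_state=None):
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        self.seen_ = {tuple(row) for row in np.asarray(X)}
        return self

    def decision_function(self, X):
        return np.array([0.5 if tuple(row) in self.seen_ else -0.5 for row in X])


def test_out_of_fold_values_come_from_unseen_models(rng):
    X = rng.normal(size=(30, 19))
    y = np.array([0, 1] * 15)
    cv = leave_10pct_out_cv(X, y, estimator=_RecordingStub(), seed=1)
    # every held-out row was absent from its fold model's training set
    assert np.all(cv["value"].to_numpy() == -0.5)
    assert cv["participant_id"].is_unique


# ---------------------------------------------------------------------------
# threshold classification and confusion metrics


def test_classify_strictly_greater_than_threshold():
    vals = np.array([-0.21, -0.20, -0.22, 0.9, -1.0])
    np.testing.assert_array_equal(
        classify(vals), [False, True, False, True, False]
    )
    assert classify(np.array([-0.999, 0.0]), threshold=-1.0).all()


def test_blinded_group_counts_reproduce_reported_metrics():
    """TP=8 TN=13 FP=4 FN=2 must give PPV 67%, NPV 87%, sensitivity 80%.

    The count-derived accuracy is (8+13)/27 = 77.8% -> 78%; this package
    reports the count-derived value (see docs on the reported-value
    discrepancy)."""
    report = report_from_counts(tp=8, tn=13, fp=4, fn=2)
    pct = report.percentages()
    assert pct["ppv"] == 67
    assert pct["npv"] == 87
    assert pct["sensitivity"] == 80
    assert pct["specificity"] == 76
    assert pct["accuracy"] == 78


def test_all_correct_predictions_give_100s():
    truth = np.array([True] * 3 + [False] * 4)
    report = confusion_metrics(truth, truth)
    pct = report.percentages()
    assert all(pct[k] == 100 for k in ("sensitivity", "specificity", "accuracy"))


def test_single_class_truth_flags_undefined_metrics():
    pred = np.array([True, True, False])
    truth = np.array([True, True, True])
    report = confusion_metrics(pred, truth)
    assert "specificity" in report.undefined
    assert np.isnan(report.specificity)
    assert report.sensitivity == pytest.approx(2 / 3)


def test_confusion_identities_hold(rng):
    pred = rng.random(200) > 0.4
    truth = rng.random(200) > 0.5
    r = confusion_metrics(pred, truth)
    # sensitivity * positives = TP (unrounded scale)
    assert r.sensitivity * (r.tp + r.fn) == pytest.approx(r.tp)
    # accuracy is the prevalence-weighted mean of sensitivity and specificity
    n = r.tp + r.tn + r.fp + r.fn
    prev = (r.tp + r.fn) / n
    assert r.accuracy == pytest.approx(prev * r.sensitivity + (1 - prev) * r.specificity)


def test_round_half_up():
    assert round_half_up(66.5) == 67
    assert round_half_up(66.49) == 66
    assert round_half_up(86.666) == 87


def test_empty_or_mismatched_inputs_rejected():
    with pytest.raises(ValueError):
        confusion_metrics(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        confusion_metrics(np.array([True]), np.array([True, False]))


# ---------------------------------------------------------------------------
# ROC / AUC


def mann_whitney_auc(values, truth):
    """Tie-corrected Mann-Whitney probability estimate (oracle)."""
    pos = values[truth]
    neg = values[~truth]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


def test_perfectly_separated_values_give_auc_one():
    vals = np.array([-0.9, -0.8, 0.8, 0.9])
    truth = np.array([False, False, True, True])
    _, auc = roc_points_auc(vals, truth)
    assert auc == 1.0


def test_trapezoid_auc_equals_mann_whitney_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(6, 30))
        vals = rng.integers(0, 6, n).astype(float)  # heavy ties
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        _, auc = roc_points_auc(vals, truth)
        assert auc == pytest.approx(mann_whitney_auc(vals, truth), abs=1e-9)


def test_auc_antisymmetry(rng):
    vals = rng.normal(size=40)
    truth = rng.random(40) < 0.4
    truth[0], truth[1] = True, False
    _, a1 = roc_points_auc(vals, truth)
    _, a2 = roc_points_auc(-vals, truth)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_permuted_labels_average_half(rng):
    vals = rng.normal(size=30)
    truth = np.array([True] * 12 + [False] * 18)
    aucs = []
    for _ in range(200):
        perm = rng.permutation(truth)
        _, a = roc_points_auc(vals, perm)
        aucs.append(a)
    se = np.std(aucs) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3


def test_single_class_roc_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_points_auc(np.array([0.1, 0.2]), np.array([True, True]))


def test_diagnostic_report_combines_threshold_and_roc(rng):
    vals = np.concatenate([rng.normal(0.4, 0.3, 25), rng.normal(-0.4, 0.3, 25)])
    truth = np.array([True] * 25 + [False] * 25)
    rep = diagnostic_report(vals, truth)
    assert rep.auc > 0.8
    assert rep.tp + rep.fn == 25
    assert len(rep.roc_points) >= 3


# ---------------------------------------------------------------------------
# forward-stepwise logistic regression


def covariate_frame(rng, n):
    return pd.DataFrame(
        {
            "gender": (rng.random(n) < 0.5).astype(float),
            "age": rng.normal(50, 12, n),
            "smoking_packyears": rng.gamma(2.0, 5.0, n),
            "toombak": (rng.random(n) < 0.4).astype(float),
        }
    )


def test_perfectly_aligned_predictor_raises_separation_flag(rng):
    n = 40
    y = np.array([0, 1] * (n // 2))
    cov = covariate_frame(rng, n)
    cov["gender"] = y.astype(float)  # complete separation
    with pytest.warns(UserWarning, match="separation"):
        result = logistic_stepwise(rng.normal(size=n), cov, y)
    assert result.separation


def test_noise_covariates_rarely_enter(rng):
    """Type-I control of the score-test entry rule at alpha = 0.05."""
    n, reps = 200, 200
    counts = {c: 0 for c in ("gender", "age", "smoking_packyears", "toombak")}
    for _ in range(reps):
        y = (rng.random(n) < 0.5).astype(int)
        enose = y * 1.2 + rng.normal(0, 1, n)  # informative e-nose value
        cov = covariate_frame(rng, n)  # pure noise
        res = logistic_stepwise(enose, cov, y)
        for c in counts:
            counts[c] += c in res.selected
    for c, k in counts.items():
        # binomial(200, 0.05): 3 SD above the mean is ~19/200
        assert k <= 20, f"{c} entered {k}/{reps} times"


def test_informative_covariates_raise_auc(rng):
    """When covariates carry independent signal, the stepwise model beats
    the e-nose value alone on average (paired over 20 replicates)."""
    diffs = []
    for rep in range(20):
        r = np.random.default_rng(rep)
        n = 120
        y = (r.random(n) < 0.5).astype(int)
        enose = 0.8 * y + r.normal(0, 1, n)
        cov = covariate_frame(r, n)
        cov["age"] = 50 + 8 * y + r.normal(0, 10, n)  # independent signal
        res = logistic_stepwise(enose, cov, y)
        _, auc_enose = roc_points_auc(enose, y == 1)
        diffs.append(res.auc - auc_enose)
    assert np.mean(diffs) > 0


def test_stepwise_requires_enough_complete_cases(rng):
    y = np.array([0, 1] * 5)
    with pytest.raises(ValueError, match="complete cases"):
        logistic_stepwise(rng.normal(size=10), covariate_frame(rng, 10), y)
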