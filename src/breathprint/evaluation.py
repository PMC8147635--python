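"""Blind-set assignment, cross-validation, and diagnostic metrics.

Conventions: ANN values live in [-1, 1]; a value strictly greater than the
operating threshold (default -0.21) is called positive.  Percentages are
rounded half-up to integers; the unrounded fractions are kept alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_curve as _sk_roc_curve
import statsmodels.api as sm

from .ann import RpropNetClassifier
from .io import SensorTensor

DEFAULT_THRESHOLD = -0.21
DEFAULT_BLOCK_SIZE = 5


# ---------------------------------------------------------------------------
# blind-set assignment by the block-size rule


def assign_blind_set(
    cohort: Sequence[SensorTensor], block_size: int = DEFAULT_BLOCK_SIZE
) -> tuple[list[SensorTensor], list[SensorTensor]]:
    """Split a cohort into (training, blinded) by the consecutive-run rule.

    Scanning in measurement order, any participant who extends a run of
    same-label measurements beyond ``block_size`` is moved to the blinded
    set (the run counter keeps counting through excluded participants and
    resets only when the other label is measured).  Deterministic; depends
    on the order only through ``order_index``.
    """
    ordered = sorted(cohort, key=lambda t: t.order_index)
    if len({t.order_index for t in ordered}) != len(ordered):
        raise ValueError("order_index must be unique within the cohort")
    training, blinded = [], []
    run_label, run_len = None, 0
    for t in ordered:
        if t.label == run_label:
            run_len += 1
        else:
            run_label, run_len = t.label, 1
        (blinded if run_len > block_size else training).append(t)
    return training, blinded


# ---------------------------------------------------------------------------
# Leave-10%-Out cross-validation


def leave_10pct_out_folds(
    labels: np.ndarray, seed: int = 0, fraction: float = 0.1, stratified: bool = True
) -> np.ndarray:
    """Fold index per participant for the Leave-10%-Out partition.

    The fold size is ceil(fraction * n); there are ceil(n / fold_size)
    folds, all of that size except a possibly smaller last one.  With
    ``stratified=True`` (default) the shuffled participants are ordered so
    classes alternate proportionally before being chunked, which keeps
    each fold's class mix close to the cohort's.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ValueError(f"Leave-10%-Out needs >= 10 participants, got {n}")
    fold_size = math.ceil(fraction * n)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if stratified and len(np.unique(labels)) > 1:
        order = []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            # proportional positions in [0, 1) give an even class interleave
            keys = (np.arange(len(idx)) + rng.random()) / len(idx)
            order.extend(zip(keys, idx))
        order.sort()
        perm = np.array([i for _, i in order])
    else:
        perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, start in enumerate(range(0, n, fold_size)):
        folds[perm[start:start + fold_size]] = f
    return folds


def leave_10pct_out_cv(
    X: np.ndarray,
    y: np.ndarray,
    estimator: RpropNetClassifier | None = None,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    fraction: float = 0.1,
    stratified: bool = True,
) -> pd.DataFrame:
    """Out-of-fold predicted values for every participant.

    Each fold's model is trained on the complement only (fold-specific
    seeds derived from ``seed``), so no participant's value comes from a
    model that saw them.  Returns a DataFrame with columns
    ``participant_id, label, value, fold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = leave_10pct_out_folds(y, seed=seed, fraction=fraction, stratified=stratified)
    est = estimator if estimator is not None else RpropNetClassifier()
    if ids is None:
        ids = [f"p{i}" for i in range(len(y))]
    values = np.full(len(y), np.nan)
    child_seeds = np.random.SeedSequence(seed).generate_state(folds.max() + 1) % (2**31)
    for f in range(folds.max() + 1):
        held = folds == f
        model = clone(est)
        model.set_params(random_state=int(child_seeds[f]))
        model.fit(X[~held], y[~held])
        values[held] = model.decision_function(X[held])
    return pd.DataFrame(
        {"participant_id": list(ids), "label": y, "value": values, "fold": folds}
    )


# ---------------------------------------------------------------------------
# threshold classification and confusion metrics


def classify(values: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean positive-calls: strictly greater than the threshold."""
    return np.asarray(values, dtype=float) > threshold


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upward (67% from 66.7)."""
    return int(math.floor(x + 0.5))


@dataclass
class DiagnosticReport:
    """Confusion-matrix counts, derived metrics, and the ROC."""

    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    undefined: list[str] = field(default_factory=list)

    def percentages(self) -> dict[str, int | None]:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if not np.isfinite(v) else round_half_up(100.0 * v)
        return out

    def to_dict(self) -> dict:
        def finite(x):
            return float(x) if np.isfinite(x) else None  # strict-JSON safe

        return {
            "threshold": self.threshold,
            "counts": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "fractions": {
                "sensitivity": finite(self.sensitivity),
                "specificity": finite(self.specificity),
                "ppv": finite(self.ppv),
                "npv": finite(self.npv),
                "accuracy": finite(self.accuracy),
            },
            "percentages": self.percentages(),
            "auc": finite(self.auc),
            "undefined": self.undefined,
        }


def confusion_metrics(
    predicted_positive: np.ndarray,
    truth_positive: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> DiagnosticReport:
    """Counts and sensitivity/specificity/PPV/NPV/accuracy from calls.

    Undefined ratios (empty denominator, e.g. single-class truth) are
    returned as ``nan`` and named in ``report.undefined``.
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(truth_positive, dtype=bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return DiagnosticReport(
        threshold=threshold,
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        undefined=undefined,
    )


def report_from_counts(tp: int, tn: int, fp: int, fn: int) -> DiagnosticReport:
    """Metrics directly from printed confusion-matrix counts."""
    pred = np.array([True] * tp + [False] * fn + [True] * fp + [False] * tn)
    truth = np.array([True] * (tp + fn) + [False] * (fp + tn))
    return confusion_metrics(pred, truth)


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points_auc(values: np.ndarray, truth_positive: np.ndarray):
    """ROC from sweeping the threshold over observed values; trapezoidal AUC.

    Raises on single-class truth.  The trapezoidal AUC equals the
    tie-corrected Mann-Whitney probability estimate.
    """
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth_positive, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), values)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def diagnostic_report(
    values: np.ndarray,
    truth_positive: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> DiagnosticReport:
    """Threshold classification + confusion metrics + ROC in one report."""
    report = confusion_metrics(classify(values, threshold), truth_positive, threshold)
    truth = np.asarray(truth_positive, dtype=bool)
    if truth.any() and not truth.all():
        report.roc_points, report.auc = roc_points_auc(values, truth_positive)
    return report


# ---------------------------------------------------------------------------
# forward-stepwise (conditional) logistic regression


class SeparationWarning(UserWarning):
    """Quasi-complete separation: coefficients diverge."""


@dataclass
class StepwiseResult:
    selected: list[str]
    params: dict[str, float]
    probabilities: np.ndarray
    roc_points: list[tuple[float, float]]
    auc: float
    separation: bool
    steps: list[dict] = field(default_factory=list)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    return res


def _score_test(y: np.ndarray, X0: np.ndarray, x_new: np.ndarray, p0: np.ndarray) -> float:
    """Rao score-test p-value for adding one column to a fitted logit."""
    w = p0 * (1.0 - p0)
    u = float(x_new @ (y - p0))
    xtw = X0 * w[:, None]
    try:
        beta = np.linalg.solve(X0.T @ xtw, xtw.T @ x_new)
    except np.linalg.LinAlgError:
        return 1.0
    resid = x_new - X0 @ beta
    v = float(resid @ (w * resid))
    if v <= 1e-12:
        return 1.0
    stat = u * u / v
    return float(stats.chi2.sf(stat, df=1))


def logistic_stepwise(
    enose_values: np.ndarray,
    covariates: pd.DataFrame,
    labels: np.ndarray,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseResult:
    """Forward-stepwise logistic regression of the label on the e-nose
    value and clinical covariates.

    Entry is by the Rao score test (p <= ``entry_p``); after each entry,
    terms whose likelihood-ratio removal test has p >= ``removal_p`` are
    dropped.  Covariates: categorical columns are 0/1-coded; incomplete
    rows must have been removed beforehand (see
    :func:`covariates_design`).  Returns the selected terms, coefficients,
    per-participant predicted probabilities, and the ROC/AUC of those
    probabilities.  Quasi-complete separation is flagged (and warned)
    rather than raised.
    """
    y = np.asarray(labels, dtype=float)
    design = covariates.astype(float).copy()
    design.insert(0, "enose", np.asarray(enose_values, dtype=float))
    if len(y) != len(design):
        raise ValueError("labels and covariates disagree in length")
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need >= 10 complete cases per class")

    n = len(y)
    intercept = np.ones((n, 1))
    selected: list[str] = []
    steps: list[dict] = []
    candidates = list(design.columns)

    def design_matrix(terms):
        if not terms:
            return intercept
        return np.column_stack([intercept, design[terms].to_numpy()])

    current = _fit_logit(y, design_matrix(selected))
    while True:
        p0 = current.predict()
        X0 = design_matrix(selected)
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        pvals = {c: _score_test(y, X0, design[c].to_numpy(dtype=float), p0) for c in remaining}
        best = min(pvals, key=pvals.get)
        if pvals[best] > entry_p:
            break
        selected.append(best)
        current = _fit_logit(y, design_matrix(selected))
        steps.append({"entered": best, "score_p": pvals[best], "llf": current.llf})
        # backward check: conditional likelihood-ratio removal test
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for term in list(selected):
                reduced = [s for s in selected if s != term]
                red_fit = _fit_logit(y, design_matrix(reduced))
                lr = 2.0 * (current.llf - red_fit.llf)
                p_rm = float(stats.chi2.sf(max(lr, 0.0), df=1))
                if p_rm >= removal_p:
                    selected.remove(term)
                    current = _fit_logit(y, design_matrix(selected))
                    steps.append({"removed": term, "lr_p": p_rm, "llf": current.llf})
                    removed = True
                    break

    separation = bool(np.any(np.abs(current.params) > 20.0)) or not np.all(
        np.isfinite(current.bse)
    )
    if separation:
        warnings.warn(
            "quasi-complete separation: coefficient estimates diverge",
            SeparationWarning,
            stacklevel=2,
        )
    probs = current.predict(design_matrix(selected))
    if (y == 1).any() and (y == 0).any():
        roc_pts, auc = roc_points_auc(probs, y == 1)
    else:  # pragma: no cover - guarded above
        roc_pts, auc = [], float("nan")
    names = ["intercept"] + selected
    params = dict(zip(names, current.params.tolist()))
    return StepwiseResult(
        selected=selected,
        params=params,
        probabilities=np.asarray(probs),
        roc_points=roc_pts,
        auc=auc,
        separation=separation,
        steps=steps,
    )


def covariates_design(cohort: Sequence[SensorTensor]) -> tuple[pd.DataFrame, np.ndarray]:
    """0/1-coded covariate table (complete cases only) and a keep-mask.

    Columns: gender (male=1), age, smoking_packyears, toombak (yes=1).
    Rows with any missing covariate are dropped listwise; the mask marks
    the retained cohort positions.
    """
    rows, keep = [], []
    for t in cohort:
        c = t.covariates
        keep.append(c.is_complete())
        if c.is_complete():
            rows.append(
                {
                    "gender": 1.0 if c.sex == "male" else 0.0,
                    "age": c.age,
                    "smoking_packyears": c.smoking_packyears,
                    "toombak": 1.0 if c.toombak_use else 0.0,
                }
            )
    return pd.DataFrame(rows), np.asarray(keep, dtype=bool)
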