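"""Classifier evaluation: the nine-metric report with bootstrap confidence
intervals, ROC/AUC, patient-level aggregation, and comparison tests
(McNemar, DeLong, Mann-Whitney U).

Slice-level ("image-based") outputs are organized into per-patient
("patient-based") predictions by averaging the voted positive probabilities
and majority-voting the binary predictions (ties -> positive class, i.e.
conservative toward detecting renal decline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .vvit import PROB_EPS

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "ppv", "npv",
                "f_score", "auc_roc", "log_loss", "kappa"]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))))


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def confusion_metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV, F-score and Cohen kappa."""
    n = cm.total
    acc = (cm.tp + cm.tn) / n
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv")
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f = float("nan")
        warnings.warn("f_score undefined; reporting NaN")
    else:
        f = 2 * ppv * sens / (ppv + sens)
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.tn + cm.fn) * (cm.tn + cm.fp)) / n ** 2
    kappa = _ratio(acc - pe, 1 - pe, "kappa")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "ppv": ppv, "npv": npv, "f_score": f, "kappa": kappa}


def roc_auc(y_true, scores) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """AUC by the Mann-Whitney rank formulation (ties count 1/2) plus the ROC
    curve from a score-threshold sweep.  Returns (auc, fpr, tpr, thresholds)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(y, s)
    return float(auc), fpr, tpr, thr


def log_loss(y_true, prob_positive) -> float:
    p = np.clip(np.asarray(prob_positive, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(y_true, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def aggregate_patient(image_probs_by_patient: Mapping[str, Sequence[float]]):
    """Patient-level probability (mean) and binary prediction (majority vote).

    Input maps patient id -> the voted positive probabilities of that
    patient's slices.  Slice binary predictions are prob >= 0.5 and the
    patient majority vote breaks ties toward the positive class.
    """
    probs: Dict[str, float] = {}
    preds: Dict[str, int] = {}
    for pid, p in image_probs_by_patient.items():
        p = np.asarray(p, dtype=np.float64)
        if p.size == 0:
            raise ValueError(f"patient {pid} has no image predictions")
        probs[pid] = float(p.mean())
        slice_preds = (p >= 0.5).astype(int)
        preds[pid] = int(slice_preds.mean() >= 0.5)
    return probs, preds


def bootstrap_ci(metric_fn: Callable[[np.ndarray], float], n_units: int,
                 B: int = 1000, seed: int = 0) -> Tuple[float, float]:
    """Nonparametric percentile bootstrap over resampling units.

    ``metric_fn`` receives an index array into the units (patients for
    patient-based analysis, slices for image-based) and may return NaN for a
    degenerate resample, which is skipped.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n_units, size=n_units)
        v = metric_fn(idx)
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """Point estimates with 95% bootstrap CIs for the nine metrics."""

    metrics: Dict[str, Tuple[float, float, float]]  # name -> (value, lo, hi)

    def value(self, name: str) -> float:
        return self.metrics[name][0]

    def to_dict(self) -> dict:
        return {k: {"value": v[0], "ci_lo": v[1], "ci_hi": v[2]}
                for k, v in self.metrics.items()}


def evaluate(y_true, prob_positive, y_pred=None, group_ids=None,
             B: int = 1000, seed: int = 0) -> MetricReport:
    """Full nine-metric report with 95% percentile-bootstrap CIs.

    If ``group_ids`` is given, bootstrap resampling is over groups
    (patients); otherwise over individual samples.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(prob_positive, dtype=np.float64)
    pred = (p >= 0.5).astype(int) if y_pred is None else np.asarray(y_pred).astype(int)

    if group_ids is None:
        units = [np.array([i]) for i in range(len(y))]
    else:
        gids = np.asarray(group_ids)
        units = [np.where(gids == g)[0] for g in pd_unique(gids)]

    def compute(rows) -> Dict[str, float]:
        cm = ConfusionMatrix.from_predictions(y[rows], pred[rows])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = confusion_metrics(cm)
            if len(np.unique(y[rows])) == 2:
                m["auc_roc"] = roc_auc(y[rows], p[rows])[0]
            else:
                m["auc_roc"] = float("nan")
        m["log_loss"] = log_loss(y[rows], p[rows])
        return m

    all_rows = np.arange(len(y))
    point = compute(all_rows)

    report = {}
    rng = np.random.default_rng(seed)
    # one shared set of resamples for all metrics (consistent and cheaper)
    resamples = [rng.integers(0, len(units), size=len(units)) for _ in range(B)]
    samples: Dict[str, List[float]] = {k: [] for k in METRIC_NAMES}
    for unit_idx in resamples:
        rows = np.concatenate([units[i] for i in unit_idx])
        if len(np.unique(y[rows])) < 2:
            continue  # degenerate resample: one class absent
        m = compute(rows)
        for k in METRIC_NAMES:
            samples[k].append(m[k])
    for k in METRIC_NAMES:
        vals = [v for v in samples[k] if np.isfinite(v)]
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
        else:
            lo = hi = float("nan")
        report[k] = (point[k], float(lo), float(hi))
    return MetricReport(metrics=report)


def pd_unique(a):
    """Order-preserving unique."""
    seen, out = set(), []
    for v in a:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# comparison tests
# ---------------------------------------------------------------------------

def mcnemar_test(model_a_correct, model_b_correct) -> float:
    """Two-sided McNemar test on paired correctness indicators.

    Exact binomial when the discordant count b+c < 25, else chi-square with
    continuity correction.  b+c = 0 carries no information -> p = 1.
    """
    a = np.asarray(model_a_correct).astype(bool)
    c_ = np.asarray(model_b_correct).astype(bool)
    if a.shape != c_.shape:
        raise ValueError("paired correctness vectors must have equal length")
    b = int(np.sum(a & ~c_))
    c = int(np.sum(~a & c_))
    if b + c == 0:
        return 1.0
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
    both = int(np.sum(a & c_))
    neither = int(np.sum(~a & ~c_))
    table = [[both, b], [c, neither]]
    exact = (b + c) < 25
    res = sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


def _placements(y, s):
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes")
    # midrank placements
    v10 = np.array([(np.sum(t > neg) + 0.5 * np.sum(t == neg)) / n for t in pos])
    v01 = np.array([(np.sum(pos > t) + 0.5 * np.sum(pos == t)) / m for t in neg])
    return v10, v01


def auc_delong_variance(y_true, scores) -> Tuple[float, float]:
    """(AUC, DeLong variance) of a single classifier via placement values."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    v10, v01 = _placements(y, s)
    auc = v10.mean()
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    return float(auc), float(var)


def delong_test(scores_a, scores_b, y_true) -> Tuple[float, float]:
    """Paired DeLong test: returns (two-sided p, auc_a - auc_b)."""
    y = np.asarray(y_true).astype(int)
    sa = np.asarray(scores_a, dtype=np.float64)
    sb = np.asarray(scores_b, dtype=np.float64)
    v10a, v01a = _placements(y, sa)
    v10b, v01b = _placements(y, sb)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return (1.0 if diff == 0 else 0.0), float(diff)
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(min(p, 1.0)), float(diff)


def mann_whitney_u(x, y) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when n_x*n_y <= 400 and tie-free,
    otherwise normal approximation with tie correction."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) * len(y) <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
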