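"""Statistical evaluation: dichotomization, diagnostics, ROC, CV, paired tests.

The diagnostic endpoint is benign vs. malignant; malignant is the positive
class throughout.  Ordinal 1–5 elastography grading scores dichotomize as
1–3 → benign, 4–5 → malignant.  Continuous metrics are evaluated with an
ROC curve; the operating cut-off is the one maximizing Youden's
J = Sen + Spe − 1 (a max-accuracy alternative is available).  Stability of
repeated selections is summarized per lesion by the coefficient of
variation (sample SD over mean of the three within-group values).

Degenerate inputs (zero-variance differences, all-tied values, empty
classes) are flagged explicitly rather than silently propagating NaN.
Reported percentages round half away from zero to 2 decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

BENIGN, MALIGNANT = "benign", "malignant"


def dichotomize(score: int) -> str:
    """Grading scores 1–3 → benign, 4–5 → malignant."""
    if score not in (1, 2, 3, 4, 5):
        raise ValueError(f"grading score must be in 1..5, got {score}")
    return BENIGN if score <= 3 else MALIGNANT


def round_pct(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of clinical tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionMatrix":
        truth, predicted = list(truth), list(predicted)
        if len(truth) != len(predicted):
            raise ValueError("label lists must have equal length")
        tp = sum(t == MALIGNANT and p == MALIGNANT for t, p in zip(truth, predicted))
        fp = sum(t == BENIGN and p == MALIGNANT for t, p in zip(truth, predicted))
        tn = sum(t == BENIGN and p == BENIGN for t, p in zip(truth, predicted))
        fn = sum(t == MALIGNANT and p == BENIGN for t, p in zip(truth, predicted))
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class Diagnostics:
    """Sen/Spe/PPV/NPV/Acc/FPR/FNR as fractions; undefined entries are None."""

    sen: Optional[float]
    spe: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    acc: float
    fpr: Optional[float]
    fnr: Optional[float]

    def as_percentages(self) -> dict:
        """Each defined metric ×100, rounded half away from zero to 2 decimals."""
        out = {}
        for name in ("sen", "spe", "ppv", "npv", "acc", "fpr", "fnr"):
            v = getattr(self, name)
            out[name] = None if v is None else round_pct(100.0 * v)
        return out


def diagnostics(cm: ConfusionMatrix) -> Diagnostics:
    """Standard confusion-matrix diagnostics; empty denominators yield None."""

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sen = ratio(cm.tp, cm.tp + cm.fn)
    spe = ratio(cm.tn, cm.tn + cm.fp)
    return Diagnostics(
        sen=sen,
        spe=spe,
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        acc=(cm.tp + cm.tn) / cm.total,
        fpr=None if spe is None else 1.0 - spe,
        fnr=None if sen is None else 1.0 - sen,
    )


@dataclass
class ROCResult:
    """AUC, Youden-optimal cut-off and its operating point."""

    auc: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str  # "higher=>malignant" or "lower=>malignant"


def auc_mann_whitney(values, labels) -> float:
    """AUC as the Mann–Whitney U statistic over n_pos·n_neg, ties counted 1/2.

    Computed with midranks; orientation is higher-value ⇒ malignant.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos, neg = values[labels == MALIGNANT], values[labels == BENIGN]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both classes present")
    ranks = stats.rankdata(values)
    r_pos = ranks[labels == MALIGNANT].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc(values, labels, cutoff_criterion: str = "youden") -> ROCResult:
    """ROC analysis of a per-lesion metric against benign/malignant labels.

    The direction is chosen so AUC >= 0.5.  Candidate cut-offs are the
    midpoints between adjacent distinct sorted values; the one maximizing
    Youden's J (or accuracy, if requested) wins, ties going to the smaller
    cut-off.  Prediction rule: malignant iff value >= cutoff (or <= for the
    reversed direction).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    auc = auc_mann_whitney(values, labels)
    higher_is_malignant = auc >= 0.5
    if not higher_is_malignant:
        auc = 1.0 - auc
    pos = values[labels == MALIGNANT]
    neg = values[labels == BENIGN]
    distinct = np.unique(values)
    if len(distinct) == 1:
        cutoffs = np.array([distinct[0]])
    else:
        cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in cutoffs:
        if higher_is_malignant:
            sen = float((pos >= c).mean())
            spe = float((neg < c).mean())
        else:
            sen = float((pos <= c).mean())
            spe = float((neg > c).mean())
        if cutoff_criterion == "youden":
            score = sen + spe - 1.0
        elif cutoff_criterion == "accuracy":
            score = (sen * len(pos) + spe * len(neg)) / (len(pos) + len(neg))
        else:
            raise ValueError(f"unknown cutoff criterion: {cutoff_criterion}")
        if best is None or score > best[0] + 1e-12:  # ties keep the smaller cutoff
            best = (score, c, sen, spe)
    _, cutoff, sen, spe = best
    return ROCResult(
        auc=auc,
        cutoff=float(cutoff),
        sens_at_cutoff=sen,
        spec_at_cutoff=spe,
        direction="higher=>malignant" if higher_is_malignant else "lower=>malignant",
    )


@dataclass
class CVRecord:
    """Per-lesion coefficient of variation of a metric's repeated values."""

    lesion_id: str
    metric: str
    cv: Optional[float]
    defined: bool


def cv_per_lesion(x1: float, x2: float, x3: float, lesion_id: str = "", metric: str = "") -> CVRecord:
    """Sample SD (n−1) over arithmetic mean of the three within-group values."""
    x = np.array([x1, x2, x3], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("CV needs three finite values")
    mean = x.mean()
    if mean == 0:
        return CVRecord(lesion_id=lesion_id, metric=metric, cv=None, defined=False)
    return CVRecord(lesion_id=lesion_id, metric=metric, cv=float(x.std(ddof=1) / mean), defined=True)


def cv_summary(table, metrics=("sar", "b_g", "mean_hue", "mean_gray")):
    """Per-group mean ± SD of per-lesion CVs over repeated images.

    ``table`` is a long/wide DataFrame with columns lesion_id, group,
    image_no and one column per metric; lesions with != 3 images in a
    group are skipped.  Returns a DataFrame indexed by (group, metric)
    with columns cv_mean, cv_sd, n_lesions — the shape of a stability
    comparison table.
    """
    import pandas as pd

    rows = []
    for (group, lesion), grp in table.groupby(["group", "lesion_id"]):
        if len(grp) != 3:
            continue
        for metric in metrics:
            if metric not in grp.columns:
                continue
            rec = cv_per_lesion(*grp[metric].to_numpy(), lesion_id=str(lesion), metric=metric)
            if rec.defined:
                rows.append({"group": group, "metric": metric, "cv": rec.cv})
    if not rows:
        raise ValueError("no lesions with exactly 3 images per group")
    df = pd.DataFrame(rows)
    out = df.groupby(["group", "metric"])["cv"].agg(cv_mean="mean", cv_sd=lambda x: x.std(ddof=1), n_lesions="size")
    return out.reset_index()


@dataclass
class TestResult:
    """Outcome of a hypothesis test; degenerate inputs are flagged."""

    statistic: Optional[float]
    pvalue: Optional[float]
    degenerate: bool = False
    note: str = ""


def paired_t(a, b) -> TestResult:
    """Paired t-test on differences a − b (df = n − 1)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            warnings.warn("paired_t: identical samples; p set to 1", stacklevel=2)
            return TestResult(statistic=0.0, pvalue=1.0, degenerate=True, note="zero differences")
        return TestResult(statistic=None, pvalue=None, degenerate=True, note="zero-variance differences")
    res = stats.ttest_rel(a, b)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def friedman(scores) -> TestResult:
    """Friedman chi-square (tie-corrected) over lesions × 3 conditions."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 2:
        raise ValueError("friedman expects an n×3 array with n >= 2")
    if np.all(X == X[:, [0]]):  # every row constant: no rank information
        return TestResult(statistic=0.0, pvalue=1.0, degenerate=True, note="all rows tied")
    res = stats.friedmanchisquare(X[:, 0], X[:, 1], X[:, 2])
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test; zero differences dropped.

    Exact null distribution for up to ``exact_max_n`` untied nonzero pairs,
    normal approximation with tie correction beyond.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("wilcoxon needs two equal-length 1-D samples")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return TestResult(statistic=None, pvalue=None, degenerate=True, note="no nonzero differences")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
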