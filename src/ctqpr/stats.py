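"""Statistical evaluation of perfusion indices against the FFR reference.

Covers the full evaluation used for a vessel-level diagnostic study of a
continuous index (here stenosis-related CT-MBF or CT-QPR) against invasive
fractional flow reserve (FFR), where FFR <= 0.80 defines hemodynamically
significant disease and a *lower* index value indicates disease:

* Spearman rank correlation between index and FFR;
* pooled-variance Student's t comparison of the two FFR groups;
* empirical ROC analysis with the Mann–Whitney (pair-counting) AUC and the
  Youden-index optimal cutoff;
* sensitivity / specificity / PPV / NPV with truncated Wald 95% CIs;
* the DeLong test for comparing two correlated (same-case) AUCs;
* ICC(2,1) interobserver agreement and the coefficient of variation with a
  normal-approximation CI;
* the closed-form binormal AUC linking two group (mean, SD) summaries to the
  AUC they imply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import DiagnosticReport, FFR_CUTOFF, InputError, QCA_FFR_BAND, VesselRecord

__all__ = [
    "label_significant",
    "ffr_eligible",
    "spearman_r",
    "two_sample_t",
    "RocCurve",
    "roc_auc",
    "youden_cutoff",
    "diagnostic_metrics",
    "compare_auc_paired",
    "icc_two_rater",
    "cv_percent",
    "binormal_auc",
    "evaluate_index",
]

Z975 = float(sps.norm.ppf(0.975))


# ---------------------------------------------------------------- labeling

def label_significant(
    records: Iterable[VesselRecord] | np.ndarray, cutoff: float = FFR_CUTOFF
) -> np.ndarray:
    """Disease labels from FFR: positive iff FFR <= cutoff (default 0.80)."""
    if isinstance(records, np.ndarray) or (
        len(records := list(records)) and not isinstance(records[0], VesselRecord)
    ):
        ffr = np.asarray(records, dtype=float)
    else:
        ffr = np.array([r.ffr for r in records], dtype=float)
    if np.any(np.isnan(ffr)):
        raise InputError("missing FFR value")
    return ffr <= cutoff


def ffr_eligible(qca_percent: float, band: tuple[float, float] = QCA_FFR_BAND) -> bool:
    """Whether a stenosis falls in the intermediate QCA band (30–69%) in which
    FFR is interrogated."""
    return band[0] <= qca_percent <= band[1]


# ------------------------------------------------------- basic inference

def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN when either vector is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("spearman_r needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t test. Returns (t, p); NaN when the
    pooled variance is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------- ROC

@dataclass
class RocCurve:
    """Empirical ROC curve of a continuous index.

    ``thresholds[i]`` classifies a case positive when its score is on the
    diseased side of the threshold (<= for lower-is-positive indices);
    ``tpr``/``fpr`` are the resulting operating points, ordered from the
    (0, 0) corner to (1, 1). ``auc`` is the Mann–Whitney pair-counting
    statistic (tied pairs count 1/2).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    lower_is_positive: bool
    n_pos: int
    n_neg: int


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise InputError("ROC analysis needs both classes present")


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    lower_is_positive: bool = True,
) -> RocCurve:
    """Empirical ROC over all unique thresholds plus the pair-counting AUC.

    The AUC is computed from mid-ranks (the Mann–Whitney U statistic with ties
    counted 1/2), which equals the trapezoidal area under the returned curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must be paired")
    _check_two_classes(labels)

    # orient so that a *higher* oriented score indicates disease
    oriented = -scores if lower_is_positive else scores
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    ranks = sps.rankdata(oriented)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-oriented, kind="stable")  # most diseased-looking first
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.diff(oriented[order]) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(~sorted_labels)[distinct]
    return RocCurve(
        thresholds=sorted_scores[distinct],
        fpr=fps / n_neg,
        tpr=tps / n_pos,
        auc=float(auc),
        lower_is_positive=lower_is_positive,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_cutoff(roc: RocCurve) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J resolve to the operating point with higher sensitivity, then to
    the less extreme threshold. The returned cutoff is the midpoint between the
    selected threshold and the next distinct score beyond it (the classifier is
    identical anywhere in that gap; for perfectly separated data this is the
    midpoint of the separating gap).
    """
    j = roc.tpr - roc.fpr  # = sensitivity + specificity - 1
    # candidate order: J desc, sensitivity desc, earlier (less extreme) first
    best = min(
        range(len(j)), key=lambda i: (-j[i], -roc.tpr[i], i)
    )
    t = float(roc.thresholds[best])
    if best + 1 < len(roc.thresholds):
        return 0.5 * (t + float(roc.thresholds[best + 1]))
    return t


def _apply_cutoff(
    scores: np.ndarray, cutoff: float, lower_is_positive: bool
) -> np.ndarray:
    return scores <= cutoff if lower_is_positive else scores >= cutoff


def _wald_ci_percent(k: int, n: int) -> tuple[float, tuple[float, float]]:
    p = k / n
    half = Z975 * np.sqrt(p * (1 - p) / n)
    lo = max(0.0, (p - half) * 100.0)
    hi = min(100.0, (p + half) * 100.0)
    return p * 100.0, (lo, hi)


def diagnostic_metrics(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> dict:
    """Sensitivity/specificity/PPV/NPV (percent) with truncated Wald 95% CIs.

    PPV (NPV) is None when no case is predicted positive (negative).
    Returns a dict with keys ``sensitivity``, ``specificity``, ``ppv``,
    ``npv`` mapping to ``(value_percent, (lo, hi))`` plus the confusion counts.
    """
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    tp = int((predictions & labels).sum())
    fn = int((~predictions & labels).sum())
    tn = int((~predictions & ~labels).sum())
    fp = int((predictions & ~labels).sum())

    out = {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": _wald_ci_percent(tp, tp + fn),
        "specificity": _wald_ci_percent(tn, tn + fp),
        "ppv": _wald_ci_percent(tp, tp + fp) if tp + fp else None,
        "npv": _wald_ci_percent(tn, tn + fn) if tn + fn else None,
    }
    return out


# --------------------------------------------------------------- DeLong

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative) for oriented
    scores where higher indicates disease; ties count 1/2."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def compare_auc_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    lower_is_positive: bool = True,
) -> tuple[float, float, float]:
    """DeLong test comparing two correlated AUCs measured on the same cases.

    Estimates the covariance of the two Mann–Whitney AUC estimators from
    placement values and returns ``(auc_a, auc_b, p)`` with a two-sided normal
    p-value for the AUC difference. Identical scores give p = 1; a degenerate
    variance with a non-zero difference gives p = NaN.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise InputError("both score vectors must cover the same cases")
    _check_two_classes(labels)
    if lower_is_positive:
        a, b = -a, -b

    v10 = np.empty((2, int(labels.sum())))
    v01 = np.empty((2, int((~labels).sum())))
    aucs = np.empty(2)
    for i, s in enumerate((a, b)):
        v10[i], v01[i], aucs[i] = _placements(s[labels], s[~labels])

    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10)      # 2x2, ddof=1
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if diff == 0.0:
        p = 1.0
    elif var_diff <= 0:
        p = float("nan")
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


def auc_ci(
    scores: Sequence[float], labels: Sequence[bool], lower_is_positive: bool = True
) -> tuple[float, tuple[float, float]]:
    """AUC with a 95% CI from the DeLong variance of a single AUC estimator."""
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    if lower_is_positive:
        s = -s
    v10, v01, auc = _placements(s[labels], s[~labels])
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = Z975 * np.sqrt(var)
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


# ------------------------------------------------------- agreement / CV

def icc_two_rater(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an (n_subjects, 2) table. Absolute agreement penalizes a
    constant bias between raters (unlike consistency ICC). Returns NaN when
    there is no variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise InputError("ratings must be an (n >= 3) x 2 table")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def cv_percent(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Coefficient of variation, 100 * SD / mean, with a 95% CI.

    The CI uses the normal-approximation standard error
    ``se = CV * sqrt(1 / (2 (n - 1))) * sqrt(1 + 2 CV^2)`` (CV as a fraction),
    truncated below at 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InputError("cv_percent needs n >= 3")
    mean = v.mean()
    if mean <= 0:
        raise InputError("cv_percent requires a positive mean")
    cv = v.std(ddof=1) / mean
    se = cv * np.sqrt(1.0 / (2.0 * (v.size - 1))) * np.sqrt(1.0 + 2.0 * cv**2)
    lo = max(0.0, (cv - Z975 * se) * 100.0)
    hi = (cv + Z975 * se) * 100.0
    return float(cv * 100.0), (float(lo), float(hi))


def binormal_auc(
    mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
) -> float:
    """Closed-form AUC of two normal score distributions.

    For diseased scores ~ N(mean_pos, sd_pos) and non-diseased ~
    N(mean_neg, sd_neg), the probability that a random diseased case looks more
    diseased than a random non-diseased one is
    ``Phi(|mean_neg - mean_pos| / sqrt(sd_pos^2 + sd_neg^2))``.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise InputError("standard deviations must be positive")
    return float(
        sps.norm.cdf(abs(mean_neg - mean_pos) / np.hypot(sd_pos, sd_neg))
    )


# ----------------------------------------------------- full evaluation

def evaluate_index(
    scores: Sequence[float],
    labels: Sequence[bool],
    index_name: str = "index",
    lower_is_positive: bool = True,
    cutoff: Optional[float] = None,
) -> DiagnosticReport:
    """Complete diagnostic evaluation of one index.

    Builds the ROC, derives the Youden cutoff (unless ``cutoff`` is given),
    re-applies it to the same cases and reports all metrics with CIs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    roc = roc_auc(scores, labels, lower_is_positive)
    if cutoff is None:
        cutoff = youden_cutoff(roc)
    preds = _apply_cutoff(scores, cutoff, lower_is_positive)
    metrics = diagnostic_metrics(preds, labels)
    auc, ci = auc_ci(scores, labels, lower_is_positive)

    def split(entry):
        return (None, None) if entry is None else entry

    ppv, ppv_ci = split(metrics["ppv"])
    npv, npv_ci = split(metrics["npv"])
    return DiagnosticReport(
        index_name=index_name,
        auc=auc,
        auc_ci=ci,
        cutoff=float(cutoff),
        sensitivity=metrics["sensitivity"][0],
        sensitivity_ci=metrics["sensitivity"][1],
        specificity=metrics["specificity"][0],
        specificity_ci=metrics["specificity"][1],
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
        n_pos=roc.n_pos,
        n_neg=roc.n_neg,
    )
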