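"""Agreement, screening and severity-estimation metrics.

AHI agreement is summarised by the Spearman rank correlation (the
estimate is heteroscedastic in the reference), the Bland-Altman bias and
limits of agreement (bias +/- 1.96 sample SD of the paired differences),
per-severity mean errors, and flags for recordings whose estimate is off
by more than 30 events/h in either direction. Screening treats AHI >=
threshold (5/15/30) as positive and reports kappa, sensitivity,
specificity, accuracy, precision, the ROC AUC from a sweep over every
distinct predicted value, and the cut closest to the perfect (1, 1)
sensitivity-specificity corner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

CANONICAL_THRESHOLDS = (5.0, 15.0, 30.0)
CONSIDERABLE_ERROR = 30.0  # events/h

_SEVERITY_ORDER = ("normal", "mild", "moderate", "severe")


def _severity(ahi: float) -> str:
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), any label alphabet.

    When both raters are constant and identical, chance agreement is 1
    and kappa is defined as 1.
    """
    a = np.asarray(list(labels_a), dtype=object)
    b = np.asarray(list(labels_b), dtype=object)
    if a.size != b.size:
        raise ValueError("label sequences must have equal length")
    if a.size == 0:
        raise ValueError("empty label sequences")
    cats = sorted(set(a) | set(b), key=str)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementReport:
    spearman_rho: float
    spearman_p: float
    bias: float
    loa_low: float
    loa_high: float
    per_severity_error: dict
    flags: list  # per recording: ok / considerably_under / considerably_over
    breusch_pagan_p: float
    differences: np.ndarray = field(repr=False, default=None)


def agreement_report(reference_ahis, predicted_ahis) -> AgreementReport:
    """AHI agreement analysis between reference and estimate.

    Differences are reference - predicted, so a difference above +30
    events/h flags considerable underestimation. The Breusch-Pagan test
    is run on the residuals of an ordinary least-squares fit of the
    estimate on the reference.
    """
    ref = np.asarray(reference_ahis, dtype=float)
    pred = np.asarray(predicted_ahis, dtype=float)
    if ref.size != pred.size or ref.size < 3:
        raise ValueError("need >= 3 paired AHI values")
    diff = ref - pred
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        warnings.warn("constant AHI sequence: Spearman undefined", stacklevel=2)
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(ref, pred)
    flags = []
    for d in diff:
        if d > CONSIDERABLE_ERROR:
            flags.append("considerably_under")
        elif d < -CONSIDERABLE_ERROR:
            flags.append("considerably_over")
        else:
            flags.append("ok")
    per_sev = {}
    sev = np.array([_severity(v) for v in ref], dtype=object)
    for s in _SEVERITY_ORDER:
        m = sev == s
        per_sev[s] = float(diff[m].mean()) if np.any(m) else np.nan

    from statsmodels.stats.diagnostic import het_breuschpagan
    import statsmodels.api as sm
    exog = sm.add_constant(ref)
    if np.ptp(ref) == 0:
        bp_p = np.nan
    else:
        resid = sm.OLS(pred, exog).fit().resid
        bp_p = float(het_breuschpagan(resid, exog)[1])
    return AgreementReport(spearman_rho=float(rho), spearman_p=float(p),
                           bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd,
                           per_severity_error=per_sev, flags=flags,
                           breusch_pagan_p=bp_p, differences=diff)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ThresholdMetrics:
    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int
    kappa: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    roc_auc: float
    optimal_cut: float
    defined: bool = True


@dataclass
class ScreeningReport:
    per_threshold: dict  # threshold -> ThresholdMetrics
    severity_confusion: np.ndarray  # 4x4 counts, rows = reference
    severity_row_percent: np.ndarray
    severity_accuracy: float


def _roc_sweep(positive: np.ndarray, score: np.ndarray):
    """ROC from a sweep over every distinct score plus +/- infinity.

    Returns (cuts, sensitivity, specificity, auc). A point's prediction
    is positive when score >= cut.
    """
    cuts = np.concatenate([[np.inf], np.unique(score)[::-1], [-np.inf]])
    sens, spec = [], []
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    for c in cuts:
        pred = score >= c
        tp = np.sum(pred & positive)
        fp = np.sum(pred & ~positive)
        sens.append(tp / n_pos if n_pos else np.nan)
        spec.append(1 - fp / n_neg if n_neg else np.nan)
    sens = np.asarray(sens)
    spec = np.asarray(spec)
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    return cuts, sens, spec, auc


def screening_report(reference_ahis, predicted_ahis,
                     thresholds=CANONICAL_THRESHOLDS) -> ScreeningReport:
    """Screening metrics at the canonical severity thresholds."""
    ref = np.asarray(reference_ahis, dtype=float)
    pred = np.asarray(predicted_ahis, dtype=float)
    if ref.size != pred.size or ref.size < 2:
        raise ValueError("need >= 2 paired AHI values")
    per = {}
    for t in thresholds:
        positive = ref >= t
        if positive.all() or not positive.any():
            per[t] = ThresholdMetrics(t, 0, 0, 0, 0, np.nan, np.nan, np.nan,
                                      np.nan, np.nan, np.nan, np.nan,
                                      defined=False)
            continue
        pred_pos = pred >= t
        tp = int(np.sum(pred_pos & positive))
        fn = int(np.sum(~pred_pos & positive))
        fp = int(np.sum(pred_pos & ~positive))
        tn = int(np.sum(~pred_pos & ~positive))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / ref.size
        ppv = tp / (tp + fp) if tp + fp else np.nan
        kappa = cohens_kappa(positive.tolist(), pred_pos.tolist())
        cuts, s_arr, sp_arr, auc = _roc_sweep(positive, pred)
        dist = np.sqrt((1 - s_arr) ** 2 + (1 - sp_arr) ** 2)
        opt = float(cuts[int(np.argmin(dist))])
        per[t] = ThresholdMetrics(t, tp, fn, fp, tn, kappa, sens, spec, acc,
                                  ppv, auc, opt)

    ref_sev = np.array([_severity(v) for v in ref], dtype=object)
    pred_sev = np.array([_severity(v) for v in pred], dtype=object)
    conf = np.zeros((4, 4), dtype=int)
    for i, s_ref in enumerate(_SEVERITY_ORDER):
        for j, s_pred in enumerate(_SEVERITY_ORDER):
            conf[i, j] = int(np.sum((ref_sev == s_ref) & (pred_sev == s_pred)))
    row_tot = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.where(row_tot > 0, 100.0 * conf / row_tot, np.nan)
    acc = float(np.trace(conf) / ref.size)
    return ScreeningReport(per_threshold=per, severity_confusion=conf,
                           severity_row_percent=row_pct,
                           severity_accuracy=acc)


def compare_correlations(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Two-sided p for equality of two correlations via Fisher's z.

    Degenerate |rho| = 1 yields infinite z; p = 0 is reported with a
    warning.
    """
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per sample")
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        warnings.warn("|rho| = 1: Fisher z infinite, reporting p = 0",
                      stacklevel=2)
        return 0.0 if rho1 != rho2 else 1.0
    z1, z2 = np.arctanh(rho1), np.arctanh(rho2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return float(2 * stats.norm.sf(abs(z)))
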