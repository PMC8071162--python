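"""Diagnostic-performance and agreement statistics.

ROC analysis treats the higher-stage group as positive and classifies
``score >= cutoff`` as positive (the imaging scores rise with disease
severity). The AUROC is the Mann-Whitney probability that a positive
case outscores a negative one (ties count half); its confidence
interval uses the DeLong structural-components variance. The operating
cutoff maximises the Youden index (sensitivity + specificity - 1) over
the midpoints of adjacent sorted unique scores, ties broken toward the
lower threshold.

Agreement between raters uses the two-way random-effects,
absolute-agreement, single-measure intraclass correlation (ICC(2,1))
computed from ANOVA mean squares, with the McGraw-Wong F-based
confidence interval, and is banded poor / moderate / good / excellent
at 0.4 / 0.6 / 0.8. Test-retest repeatability is the mean per-subject
coefficient of variation in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError, HepaquantError


@dataclass
class RocResult:
    auroc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    diagnostic_accuracy: float
    counts: tuple[int, int, int, int]  # TP, FP, TN, FN
    n_pos: int
    n_neg: int
    auroc_ci: Optional[tuple[float, float]] = None


@dataclass
class AgreementResult:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    reliability_band: str
    mean_cv_percent: Optional[float] = None
    model: str = "two-way random, absolute agreement, single measure (ICC(2,1))"


def auroc(scores_neg, scores_pos) -> float:
    """Mann-Whitney AUROC: P(pos > neg) + 0.5 P(pos == neg)."""
    neg = np.asarray(scores_neg, dtype=float)
    pos = np.asarray(scores_pos, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise HepaquantError("both groups must be nonempty")
    # rank-based U statistic; exact for ties
    combined = np.concatenate([neg, pos])
    ranks = stats.rankdata(combined)
    r_pos = ranks[neg.size :].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (neg.size * pos.size))


def _delong_ci(neg: np.ndarray, pos: np.ndarray, alpha: float = 0.05):
    """DeLong variance of the AUROC via structural components."""
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # per-positive component
    v01 = psi.mean(axis=0)  # per-negative component
    m, n = len(pos), len(neg)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def _confusion(neg: np.ndarray, pos: np.ndarray, cutoff: float):
    tp = int(np.sum(pos >= cutoff))
    fn = len(pos) - tp
    fp = int(np.sum(neg >= cutoff))
    tn = len(neg) - fp
    return tp, fp, tn, fn


def best_cutoff(scores_neg, scores_pos, ci_alpha: float = 0.05) -> RocResult:
    """Youden-optimal operating point with the full diagnostic metric set.

    Candidate thresholds are the midpoints of adjacent sorted unique
    pooled scores; equal Youden indices resolve to the lowest threshold.
    """
    neg = np.asarray(scores_neg, dtype=float)
    pos = np.asarray(scores_pos, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise HepaquantError("both groups must be nonempty")
    uniq = np.unique(np.concatenate([neg, pos]))
    if uniq.size < 2:
        raise DegenerateInputError("all scores identical: no separating threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for cut in candidates:  # ascending, so ties keep the lower threshold
        tp, fp, tn, fn = _confusion(neg, pos, cut)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        youden = sens + spec - 1.0
        if best is None or youden > best[0] + 1e-12:
            best = (youden, cut, tp, fp, tn, fn, sens, spec)
    _, cut, tp, fp, tn, fn, sens, spec = best
    total = tp + fp + tn + fn
    auc, ci = _delong_ci(neg, pos, alpha=ci_alpha)
    return RocResult(
        auroc=auc,
        cutoff=float(cut),
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        diagnostic_accuracy=(tp + tn) / total,
        counts=(tp, fp, tn, fn),
        n_pos=len(pos),
        n_neg=len(neg),
        auroc_ci=ci,
    )


def reliability_band(icc: float) -> str:
    if icc < 0.4:
        return "poor"
    if icc < 0.6:
        return "moderate"
    if icc < 0.8:
        return "good"
    return "excellent"


def icc_absolute_agreement(
    ratings: np.ndarray, alpha: float = 0.05, mean_cv_percent: Optional[float] = None
) -> AgreementResult:
    """ICC(2,1) from a complete subjects x raters table.

    Two-way random effects, absolute agreement, single measure:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the rows (subjects), columns (raters) and residual
    mean squares. The CI follows McGraw & Wong's F approximation with
    Satterthwaite degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise DomainError(f"ratings must be a 2-D table, got shape {x.shape}")
    n, k = x.shape
    if n < 5 or k < 2:
        raise DomainError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise DomainError("ratings table has missing or non-finite cells")

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

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateInputError("ratings table has no variance")
    icc = (msr - mse) / denom

    # McGraw-Wong CI for ICC(A,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:  # perfect agreement: interval collapses
        lower = upper = icc
    return AgreementResult(
        icc=float(icc),
        icc_ci_low=float(lower),
        icc_ci_high=float(upper),
        reliability_band=reliability_band(float(icc)),
        mean_cv_percent=mean_cv_percent,
    )


def repeatability_cv(repeated: np.ndarray, ddof: int = 1) -> float:
    """Mean per-subject CV (percent) over a subjects x repeats table."""
    x = np.asarray(repeated, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DomainError("need a subjects x repeats table with >= 2 repeats")
    means = x.mean(axis=1)
    if np.any(means == 0):
        raise DomainError("a subject's mean is zero; CV undefined")
    cvs = x.std(axis=1, ddof=ddof) / np.abs(means) * 100.0
    return float(cvs.mean())
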