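"""Single-feature discrimination analysis between low- and high-grade tumors.

For each heterogeneity feature: a two-group location test (Welch t when
both groups look normal by Shapiro-Wilk at alpha = 0.05, Mann-Whitney U
otherwise), the empirical ROC with its AUC and DeLong 95% confidence
interval, and the Youden-optimal operating point (sensitivity, specificity,
J = sensitivity + specificity − 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, LabelError, ParameterError

__all__ = [
    "FeatureScreenResult",
    "choose_test",
    "single_feature_roc",
    "youden_index",
    "screen_cohort",
    "delong_auc_ci",
    "screen_results_to_frame",
]


@dataclass(frozen=True)
class FeatureScreenResult:
    """Discrimination summary of one feature (one row of a Table-2-style report)."""

    feature_name: str
    test_used: str  # "t-test" | "U-test"
    p_value: float
    auc: float
    auc_ci: tuple[float, float]
    specificity: float
    sensitivity: float
    youden: float
    threshold: float
    direction: str  # "greater": high values call high grade; "less": reversed
    significant: bool = False


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity − 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def choose_test(
    values_low: np.ndarray,
    values_high: np.ndarray,
    normality_alpha: float = 0.05,
) -> tuple[str, float]:
    """Two-group test selected by a per-group Shapiro-Wilk normality check.

    Both groups normal → two-sided Welch t-test; otherwise two-sided
    Mann-Whitney U.  Returns ``(test_used, p_value)``.
    """
    lo = np.asarray(values_low, dtype=float)
    hi = np.asarray(values_high, dtype=float)
    if lo.size < 3 or hi.size < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per group, got {lo.size} and {hi.size}"
        )

    def _normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:  # constant sample: Shapiro undefined, clearly non-normal fit
            return False
        return stats.shapiro(v).pvalue >= normality_alpha

    if _normal(lo) and _normal(hi):
        p = stats.ttest_ind(lo, hi, equal_var=False).pvalue
        return "t-test", float(p)
    if np.ptp(np.concatenate([lo, hi])) == 0:
        return "U-test", 1.0  # all observations identical: no evidence of shift
    p = stats.mannwhitneyu(lo, hi, alternative="two-sided").pvalue
    return "U-test", float(p)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval for one score vector.

    Uses the structural-component (midrank) formulation; the point estimate
    equals the Mann-Whitney AUC.  Degenerate zero variance (e.g. perfect
    separation) collapses the interval onto the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise LabelError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-positive structural components
    v10 = 1.0 - (tz[m:] - ty) / m  # per-negative
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return float(auc), (float(lo), float(hi))


def single_feature_roc(
    values: np.ndarray,
    labels: np.ndarray,
    positive_direction: str = "auto",
    feature_name: str = "",
) -> FeatureScreenResult:
    """Empirical ROC of one feature against the binary grade label.

    ``positive_direction='auto'`` orients the feature so AUC >= 0.5;
    the operating point maximises Youden's J (ties broken toward higher
    specificity); the 95% CI is DeLong's.  The p-value field is filled by
    :func:`screen_cohort`; here it is NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise LabelError(f"labels must be binary 0/1, got {np.unique(labels)}")
    if not ((labels == 0).any() and (labels == 1).any()):
        raise LabelError("both classes must be present")

    auc_raw, _ = delong_auc_ci(values, labels)
    if positive_direction == "auto":
        direction = "greater" if auc_raw >= 0.5 else "less"
    elif positive_direction in ("greater", "less"):
        direction = positive_direction
    else:
        raise ParameterError(f"unknown positive_direction {positive_direction!r}")
    scores = values if direction == "greater" else -values

    auc, ci = delong_auc_ci(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    # max J; ties go to the lowest fpr (highest specificity)
    best = min(np.flatnonzero(j == j.max()), key=lambda i: (fpr[i], -tpr[i]))
    sens, spec = float(tpr[best]), float(1.0 - fpr[best])
    thr = float(thresholds[best])
    if direction == "less":
        thr = -thr  # cutoff back in feature units; call positive when value <= thr
    return FeatureScreenResult(
        feature_name=feature_name,
        test_used="",
        p_value=float("nan"),
        auc=float(auc),
        auc_ci=ci,
        specificity=spec,
        sensitivity=sens,
        youden=youden_index(sens, spec),
        threshold=thr,
        direction=direction,
    )


def screen_cohort(
    features: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[FeatureScreenResult]:
    """Screen every feature column: group test + single-feature ROC.

    Significance is flagged at two-sided ``alpha`` (no multiple-testing
    correction by default; ``correction='fdr_bh'`` applies
    Benjamini-Hochberg across features).
    """
    labels = np.asarray(labels)
    results = []
    pvals = []
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        test_used, p = choose_test(v[labels == 0], v[labels == 1])
        r = single_feature_roc(v, labels, feature_name=name)
        results.append((r, test_used, p))
        pvals.append(p)
    if correction == "fdr_bh":
        flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    elif correction is None:
        flags = [p < alpha for p in pvals]
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    out = []
    for (r, test_used, p), sig in zip(results, flags):
        out.append(
            FeatureScreenResult(
                feature_name=r.feature_name,
                test_used=test_used,
                p_value=p,
                auc=r.auc,
                auc_ci=r.auc_ci,
                specificity=r.specificity,
                sensitivity=r.sensitivity,
                youden=r.youden,
                threshold=r.threshold,
                direction=r.direction,
                significant=bool(sig),
            )
        )
    return out


def screen_results_to_frame(results: list[FeatureScreenResult]) -> pd.DataFrame:
    """Tabular screening report (one row per feature, Table-2-style columns)."""
    return pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "auc": [r.auc for r in results],
            "auc_ci_low": [r.auc_ci[0] for r in results],
            "auc_ci_high": [r.auc_ci[1] for r in results],
            "specificity": [r.specificity for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "youden_index": [r.youden for r in results],
            "p_value": [r.p_value for r in results],
            "test_used": [r.test_used for r in results],
            "significant": [r.significant for r in results],
        }
    )
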