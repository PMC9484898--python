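"""Clinical-style evaluation of predicted probabilities.

Three complementary views of a fitted model's output on a labeled set:
the ROC curve with AUC, DeLong 95% CI and Youden operating point; a
binned reliability (calibration) curve on equal-count probability bins;
and decision curve analysis (DCA), plotting the net benefit

    NB(p_t) = TP/n − (FP/n) · p_t / (1 − p_t)

of calling high-grade at threshold probability p_t, against the
treat-all and treat-none strategies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import LabelError, ParameterError
from .screening import FeatureScreenResult, single_feature_roc

__all__ = [
    "EvalReport",
    "evaluate_roc",
    "calibration_curve",
    "decision_curve",
    "evaluate_model",
    "plot_roc",
    "plot_calibration",
    "plot_decision_curve",
]


@dataclass
class EvalReport:
    """Full evaluation of one probability vector against binary labels."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    calibration_bins: list[tuple[float, float, int]]
    dca_thresholds: list[float]
    dca_net_benefit_model: list[float]
    dca_net_benefit_all: list[float]
    dca_net_benefit_none: list[float]
    n: int
    prevalence: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _check_probs(probabilities: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ParameterError("probabilities must lie in [0, 1]")
    return p


def evaluate_roc(probabilities, labels) -> FeatureScreenResult:
    """ROC of predicted probabilities (direction fixed: higher = high grade).

    Shares its implementation with the single-feature screen, so AUC,
    DeLong CI and the Youden operating point follow identical conventions.
    """
    return single_feature_roc(
        np.asarray(probabilities, dtype=float),
        np.asarray(labels),
        positive_direction="greater",
        feature_name="model_probability",
    )


def calibration_curve(
    probabilities, labels, n_bins: int = 10, strategy: str = "quantile"
) -> list[tuple[float, float, int]]:
    """Reliability bins: (mean predicted probability, observed fraction, count).

    Equal-count (quantile) bins by default; ``strategy='uniform'`` uses
    equal-width bins on [0, 1].  Empty bins are omitted; duplicate
    quantile edges collapse, so fewer than ``n_bins`` bins may return.
    """
    p = _check_probs(probabilities)
    y = np.asarray(labels)
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if strategy == "quantile":
        edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    elif strategy == "uniform":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    if edges.size < 2:  # all probabilities identical
        return [(float(p.mean()), float(y.mean()), int(y.size))]
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    bins = []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.any():
            bins.append((float(p[sel].mean()), float(y[sel].mean()), int(sel.sum())))
    return bins


def decision_curve(
    probabilities,
    labels,
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Net benefit of the model, treat-all and treat-none across thresholds.

    A case is called positive when its probability >= p_t.  Returns
    ``(thresholds, nb_model, nb_all, nb_none)``.
    """
    p = _check_probs(probabilities)
    y = np.asarray(labels)
    if not ((y == 0).any() and (y == 1).any()):
        raise LabelError("both classes must be present")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if ((t <= 0) | (t >= 1)).any():
        raise ParameterError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prevalence = y.mean()
    odds = t / (1.0 - t)
    calls = p[None, :] >= t[:, None]  # (T, n)
    tp = (calls & (y == 1)[None, :]).sum(axis=1) / n
    fp = (calls & (y == 0)[None, :]).sum(axis=1) / n
    nb_model = tp - fp * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    nb_none = np.zeros_like(t)
    return t, nb_model, nb_all, nb_none


def evaluate_model(probabilities, labels, n_bins: int = 10) -> EvalReport:
    """Assemble the full evaluation report for one probability vector."""
    p = _check_probs(probabilities)
    y = np.asarray(labels)
    roc = evaluate_roc(p, y)
    bins = calibration_curve(p, y, n_bins=n_bins)
    t, nb_m, nb_a, nb_n = decision_curve(p, y)
    return EvalReport(
        auc=roc.auc,
        auc_ci=roc.auc_ci,
        sensitivity=roc.sensitivity,
        specificity=roc.specificity,
        threshold=roc.threshold,
        calibration_bins=[tuple(b) for b in bins],
        dca_thresholds=t.tolist(),
        dca_net_benefit_model=nb_m.tolist(),
        dca_net_benefit_all=nb_a.tolist(),
        dca_net_benefit_none=nb_n.tolist(),
        n=int(y.size),
        prevalence=float(y.mean()),
    )


# ---------------------------------------------------------------- plotting


def _get_axes(ax):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    return ax


def plot_roc(probabilities, labels, ax=None, label: str | None = None):
    from sklearn.metrics import roc_curve

    ax = _get_axes(ax)
    fpr, tpr, _ = roc_curve(labels, probabilities)
    roc = evaluate_roc(probabilities, labels)
    ax.plot(fpr, tpr, label=label or f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_calibration(probabilities, labels, n_bins: int = 10, ax=None):
    ax = _get_axes(ax)
    bins = calibration_curve(probabilities, labels, n_bins=n_bins)
    xs = [b[0] for b in bins]
    ys = [b[1] for b in bins]
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(xs, ys, "o-", label="model")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed high-grade fraction")
    ax.legend(loc="upper left")
    return ax


def plot_decision_curve(probabilities, labels, ax=None):
    ax = _get_axes(ax)
    t, nb_m, nb_a, nb_n = decision_curve(probabilities, labels)
    ax.plot(t, nb_m, label="model")
    ax.plot(t, nb_a, label="treat all")
    ax.plot(t, nb_n, "k--", lw=0.8, label="treat none")
    ax.set_ylim(bottom=max(-0.1, min(nb_m.min(), -0.02)))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(loc="upper right")
    return ax
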