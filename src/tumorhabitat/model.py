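"""Cohort splitting, normalization, feature selection and the grade classifier.

The classifier follows the study design the pipeline implements: a 7:3
stratified random split of the cohort, per-feature z-scoring fitted on the
training partition only, an optional feature-selection chain (ANOVA screen,
L1-penalized logistic ("lasso"), Pearson-correlation filter, PCA), and a
Gaussian-process classifier with an RBF kernel whose posterior probability
of high grade is thresholded at the Youden-optimal training cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .errors import (
    DataError,
    LabelError,
    ParameterError,
    SchemaError,
    SelectionEmptyError,
    StratificationError,
)
from .metrics import FEATURE_NAMES
from .screening import choose_test, single_feature_roc

__all__ = [
    "SplitCohort",
    "split_cohort",
    "ZScoreScaler",
    "FeatureSelector",
    "GradeClassifier",
    "fit_classifier",
    "predict_proba",
    "PAPER_FEATURE_SET",
    "save_model",
    "load_model",
]

#: the four-index feature set the final published model was built on
PAPER_FEATURE_SET = (
    "inertia",
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
)


@dataclass
class SplitCohort:
    """A stratified training/test partition of the labeled feature table."""

    train_features: pd.DataFrame
    train_labels: np.ndarray
    test_features: pd.DataFrame
    test_labels: np.ndarray
    split_ratio: float
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.train_features)

    @property
    def n_test(self) -> int:
        return len(self.test_features)


def split_cohort(
    features: pd.DataFrame,
    labels: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
) -> SplitCohort:
    """Stratified random split with |training| = round(ratio x n).

    120 cases at the default 7:3 ratio give 84 training and 36 test cases.
    Deterministic given ``seed``; raises if either class has < 2 cases.
    """
    labels = np.asarray(labels)
    if len(features) != labels.size:
        raise DataError("feature table and labels disagree in length")
    if not 0.0 < ratio < 1.0:
        raise ParameterError(f"ratio must lie in (0, 1), got {ratio}")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise StratificationError(
            f"each class needs >= 2 cases for a stratified split (counts {dict(zip(classes, counts))})"
        )
    n_train = int(round(ratio * len(features)))
    if n_train < classes.size or len(features) - n_train < classes.size:
        raise StratificationError("partition too small to contain both classes")
    idx_train, idx_test = train_test_split(
        np.arange(len(features)),
        train_size=n_train,
        stratify=labels,
        random_state=seed,
    )
    idx_train, idx_test = np.sort(idx_train), np.sort(idx_test)
    return SplitCohort(
        train_features=features.iloc[idx_train],
        train_labels=labels[idx_train],
        test_features=features.iloc[idx_test],
        test_labels=labels[idx_test],
        split_ratio=ratio,
        seed=seed,
    )


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Per-feature standardization with the sample-sd (n−1) convention.

    Fitted on training data only; zero-variance features are dropped with a
    warning rather than producing NaNs.  ``transform`` returns a DataFrame
    restricted to the retained features.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = _as_frame(X)
        if len(X) < 2:
            raise DataError("need >= 2 cases to fit a scaler")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        degenerate = sd[sd == 0].index.tolist()
        if degenerate:
            warnings.warn(
                f"dropping zero-variance feature(s): {degenerate}", UserWarning
            )
        keep = [c for c in X.columns if c not in degenerate]
        if not keep:
            raise SelectionEmptyError("every feature has zero variance")
        self.feature_names_ = list(keep)
        self.mean_ = mean[keep].to_numpy()
        self.scale_ = sd[keep].to_numpy()
        self.dropped_ = degenerate
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = _as_frame(X)
        missing = set(self.feature_names_) - set(X.columns)
        if missing:
            raise SchemaError(f"missing feature(s): {sorted(missing)}")
        Z = (X[self.feature_names_] - self.mean_) / self.scale_
        return Z


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(FEATURE_NAMES[: X.shape[1]]) if X.shape[1] <= len(FEATURE_NAMES) else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return pd.DataFrame(X, columns=names)


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Left-to-right feature-selection chain on standardized training data.

    Steps:

    - ``"anova"`` — univariate screen: keep features whose two-group test
      (t or U, chosen per group normality) has p < ``alpha``;
    - ``"lasso"`` — L1-penalized logistic regression, penalty chosen by
      seeded stratified CV; keep features with nonzero coefficients;
    - ``"pcc"`` — among any pair with \\|Pearson r\\| > ``corr_threshold``,
      drop the member with the lower single-feature AUC;
    - ``"pca"`` — project onto the leading principal components explaining
      >= ``pca_variance`` of the variance (output columns ``pc1..pcM``).

    An explicit ``override`` feature list bypasses the chain entirely.
    """

    def __init__(
        self,
        chain: tuple[str, ...] = ("anova", "lasso"),
        override: tuple[str, ...] | None = None,
        alpha: float = 0.05,
        corr_threshold: float = 0.9,
        pca_variance: float = 0.95,
        random_state: int | None = None,
    ) -> None:
        self.chain = chain
        self.override = override
        self.alpha = alpha
        self.corr_threshold = corr_threshold
        self.pca_variance = pca_variance
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if self.override is not None:
            missing = set(self.override) - set(X.columns)
            if missing:
                raise SchemaError(f"override names unknown feature(s): {sorted(missing)}")
            self.selected_features_ = list(self.override)
            self.pca_ = None
            return self
        cols = list(X.columns)
        self.pca_ = None
        for step in self.chain:
            if not cols:
                break
            sub = X[cols]
            if step == "anova":
                cols = [
                    c
                    for c in cols
                    if choose_test(
                        sub[c].to_numpy()[y == 0], sub[c].to_numpy()[y == 1]
                    )[1]
                    < self.alpha
                ]
            elif step == "lasso":
                lr = LogisticRegressionCV(
                    penalty="l1",
                    solver="liblinear",
                    Cs=10,
                    scoring="neg_log_loss",
                    cv=StratifiedKFold(5, shuffle=True, random_state=self.random_state),
                    max_iter=2000,
                ).fit(sub.to_numpy(), y)
                cols = [c for c, w in zip(cols, lr.coef_.ravel()) if w != 0.0]
            elif step == "pcc":
                cols = self._pcc_filter(sub, y)
            elif step == "pca":
                pca = PCA(n_components=self.pca_variance, svd_solver="full")
                pca.fit(sub.to_numpy())
                self.pca_ = (pca, cols)
                cols = [f"pc{i + 1}" for i in range(pca.n_components_)]
                self.selected_features_ = cols
                return self  # pca must be terminal: outputs are components
            else:
                raise ParameterError(f"unknown selection step {step!r}")
        if not cols:
            raise SelectionEmptyError(
                f"selection chain {self.chain} removed every feature"
            )
        self.selected_features_ = cols
        return self

    def _pcc_filter(self, X: pd.DataFrame, y: np.ndarray) -> list[str]:
        cols = list(X.columns)
        aucs = {
            c: single_feature_roc(X[c].to_numpy(), y, feature_name=c).auc for c in cols
        }
        corr = X.corr().abs()
        keep = list(cols)
        # repeatedly resolve the most correlated offending pair
        changed = True
        while changed and len(keep) > 1:
            changed = False
            for i, a in enumerate(keep):
                for b in keep[i + 1 :]:
                    if corr.loc[a, b] > self.corr_threshold:
                        drop = a if aucs[a] < aucs[b] else b
                        keep.remove(drop)
                        changed = True
                        break
                if changed:
                    break
        return keep

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_features_")
        X = _as_frame(X)
        if self.pca_ is not None:
            pca, cols = self.pca_
            missing = set(cols) - set(X.columns)
            if missing:
                raise SchemaError(f"missing feature(s): {sorted(missing)}")
            comps = pca.transform(X[cols].to_numpy())
            return pd.DataFrame(
                comps, columns=self.selected_features_, index=X.index
            )
        missing = set(self.selected_features_) - set(X.columns)
        if missing:
            raise SchemaError(f"missing feature(s): {sorted(missing)}")
        return X[self.selected_features_]


class GradeClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian-process grade classifier over heterogeneity features.

    The estimator bundles the training-only preprocessing (z-score scaler,
    feature subset or selection chain) with a GP classifier using a
    constant x RBF kernel (single length scale initialized at 1), marginal-
    likelihood optimization with seeded restarts, and the Laplace
    approximation to the non-Gaussian likelihood (sklearn's implementation).

    Parameters
    ----------
    features : tuple of str or None
        Explicit feature subset; the default is the four-index set
        :data:`PAPER_FEATURE_SET`.  Set to ``None`` with a
        ``selection_chain`` to select data-adaptively.
    selection_chain : tuple of str or None
        Passed to :class:`FeatureSelector` when ``features`` is ``None``.
    threshold_policy : {"youden", "fixed"}
        Probability cutoff for ``predict``: Youden-optimal on the training
        ROC, or a fixed 0.5.
    n_restarts_optimizer : int
        Kernel hyperparameter optimizer restarts.
    random_state : int or None
        Fixes optimizer restarts and selection CV.

    Attributes
    ----------
    scaler_, selector_, gpc_ : fitted sub-estimators
    selected_features_ : list of str
    threshold_ : float, probability cutoff used by ``predict``
    classes_ : array([0, 1])
    """

    def __init__(
        self,
        features: tuple[str, ...] | None = PAPER_FEATURE_SET,
        selection_chain: tuple[str, ...] | None = None,
        threshold_policy: str = "youden",
        n_restarts_optimizer: int = 3,
        random_state: int | None = None,
    ) -> None:
        self.features = features
        self.selection_chain = selection_chain
        self.threshold_policy = threshold_policy
        self.n_restarts_optimizer = n_restarts_optimizer
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise LabelError("training set contains a single class")
        if np.isnan(X.to_numpy(dtype=float)).any():
            raise DataError("missing feature values in training set")
        self.scaler_ = ZScoreScaler().fit(X)
        Z = self.scaler_.transform(X)
        if self.features is not None:
            selector = FeatureSelector(override=tuple(self.features))
        else:
            chain = self.selection_chain or ("anova", "lasso")
            selector = FeatureSelector(chain=tuple(chain), random_state=self.random_state)
        self.selector_ = selector.fit(Z, y)
        Zs = self.selector_.transform(Z)
        self.selected_features_ = list(self.selector_.selected_features_)
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
        self.gpc_ = GaussianProcessClassifier(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts_optimizer,
            random_state=self.random_state,
        ).fit(Zs.to_numpy(), y)
        self.classes_ = self.gpc_.classes_
        train_p = self.gpc_.predict_proba(Zs.to_numpy())[:, 1]
        if self.threshold_policy == "youden":
            r = single_feature_roc(train_p, y, positive_direction="greater")
            self.threshold_ = r.threshold
            self.train_auc_ = r.auc
        elif self.threshold_policy == "fixed":
            self.threshold_ = 0.5
            self.train_auc_ = single_feature_roc(
                train_p, y, positive_direction="greater"
            ).auc
        else:
            raise ParameterError(f"unknown threshold_policy {self.threshold_policy!r}")
        return self

    def _transform(self, X) -> np.ndarray:
        check_is_fitted(self, "gpc_")
        X = _as_frame(X)
        return self.selector_.transform(self.scaler_.transform(X)).to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) array of [P(low grade), P(high grade)]."""
        return self.gpc_.predict_proba(self._transform(X))

    def predict(self, X) -> np.ndarray:
        """Binary grade calls at the fitted probability threshold."""
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold_).astype(int)


def fit_classifier(
    train_features: pd.DataFrame,
    train_labels: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> GradeClassifier:
    """Fit the default GP grade classifier (thin wrapper over the estimator)."""
    return GradeClassifier(random_state=seed, **kwargs).fit(train_features, train_labels)


def predict_proba(model: GradeClassifier, features: pd.DataFrame) -> np.ndarray:
    """Probability of high grade (label 1) per case."""
    return model.predict_proba(features)[:, 1]


_ARTIFACT_VERSION = 1


def save_model(model: GradeClassifier, path: str | Path) -> None:
    """Serialize the fitted model to one versioned JSON artifact.

    Stores scaler parameters, the selected feature list, the optimized
    kernel hyperparameters, and the (standardized) training inputs/targets;
    :func:`load_model` rebuilds the GP by refitting with the stored kernel
    fixed, which is deterministic and keeps the artifact plain text.
    """
    check_is_fitted(model, "gpc_")
    if model.selector_.pca_ is not None:
        raise ParameterError("PCA-based models are not serializable to the JSON artifact")
    Xtr = model.gpc_.base_estimator_.X_train_
    ytr = model.gpc_.base_estimator_.y_train_
    payload = {
        "version": _ARTIFACT_VERSION,
        "scaler": {
            "feature_names": model.scaler_.feature_names_,
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
        },
        "selected_features": model.selected_features_,
        "kernel_theta": model.gpc_.kernel_.theta.tolist(),
        "threshold": model.threshold_,
        "threshold_policy": model.threshold_policy,
        "train_X": np.asarray(Xtr).tolist(),
        "train_y": np.asarray(ytr).tolist(),
        "random_state": model.random_state,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> GradeClassifier:
    """Rebuild a fitted :class:`GradeClassifier` from its JSON artifact."""
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != _ARTIFACT_VERSION:
        raise DataError(f"unsupported artifact version {payload.get('version')!r}")
    model = GradeClassifier(
        features=tuple(payload["selected_features"]),
        threshold_policy=payload["threshold_policy"],
        random_state=payload["random_state"],
    )
    scaler = ZScoreScaler()
    scaler.feature_names_ = list(payload["scaler"]["feature_names"])
    scaler.mean_ = np.asarray(payload["scaler"]["mean"])
    scaler.scale_ = np.asarray(payload["scaler"]["scale"])
    scaler.dropped_ = []
    model.scaler_ = scaler
    selector = FeatureSelector(override=tuple(payload["selected_features"]))
    selector.selected_features_ = list(payload["selected_features"])
    selector.pca_ = None
    model.selector_ = selector
    model.selected_features_ = list(payload["selected_features"])
    kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
    kernel.theta = np.asarray(payload["kernel_theta"])
    gpc = GaussianProcessClassifier(kernel=kernel, optimizer=None)
    gpc.fit(np.asarray(payload["train_X"]), np.asarray(payload["train_y"]))
    model.gpc_ = gpc
    model.classes_ = gpc.classes_
    model.threshold_ = float(payload["threshold"])
    return model
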