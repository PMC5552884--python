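"""Correctness-trained logistic confidence weights.

A per-participant logistic model maps the feature vector of a decision to
the probability ``w`` in [0, 1] that the decision was correct.  Training
labels come from correctness: correct decisions are the "confident" class
(label -1), incorrect decisions the "non-confident" class (+1).  The L2
regularisation strength ``C`` is chosen from {1e-4, ..., 1e4} by stratified
inner cross-validation scored with logistic loss (288 training trials split
192 fit / 96 validate per inner fold), then the model is refit on all
training trials with the selected ``C``.

Features are z-scored on training statistics before the fit; inside the
inner CV the standardisation is recomputed per fold from the fold's fitting
trials only, so hyperparameter selection never sees validation statistics.
"""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateTrainingError, InputError

logger = logging.getLogger(__name__)

#: Candidate regularisation strengths.
C_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-4, 5))

#: Label convention: correct decisions are the "confident" class.
LABEL_CONFIDENT = -1
LABEL_NONCONFIDENT = 1


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


class ConfidenceEstimator(ClassifierMixin, BaseEstimator):
    """Logistic decision-confidence model with inner-CV selection of ``C``.

    Parameters
    ----------
    C : float or None
        Fixed regularisation strength; ``None`` (default) selects from
        ``C_grid`` by stratified inner cross-validation on logistic loss.
        Ties are broken toward the smallest (most regularised) ``C``.
    C_grid : sequence of float
    n_inner_folds : int
        Inner folds (default 3: 288 trials -> 192 fit / 96 validate).  The
        effective fold count never exceeds the minority-class count; with a
        minority of 2 this degrades to leave-one-minority-out.  With a
        single minority trial, selection is skipped and ``C`` falls back to
        1.0 (logged).
    standardize : bool
        z-score features on training statistics (default True).

    Attributes
    ----------
    C_ : float               selected regularisation strength
    coef_, intercept_ :      logistic parameters in standardised feature space
    mean_, scale_ :          training standardisation parameters
    classes_ :               ``[-1, 1]`` (confident, non-confident)
    inner_losses_ :          mean held-out log-loss per candidate ``C``
    """

    def __init__(
        self,
        C: float | None = None,
        C_grid: Sequence[float] = C_GRID,
        n_inner_folds: int = 3,
        standardize: bool = True,
        max_iter: int = 2000,
        tol: float = 1e-8,
    ) -> None:
        self.C = C
        self.C_grid = C_grid
        self.n_inner_folds = n_inner_folds
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _make_lr(self, C: float) -> LogisticRegression:
        # default penalty is L2; strength is governed by C alone
        return LogisticRegression(C=C, solver="lbfgs", max_iter=self.max_iter, tol=self.tol)

    def _prep(self, X: np.ndarray, fit_stats: tuple | None = None) -> np.ndarray:
        if not self.standardize:
            return X
        if fit_stats is None:
            fit_stats = _standardize_params(X)
        mean, scale = fit_stats
        return (X - mean) / scale

    def _select_C(self, X: np.ndarray, y: np.ndarray) -> float:
        minority = int(min(np.sum(y == c) for c in np.unique(y)))
        if minority < 2:
            logger.warning(
                "confidence fit: only %d minority trial(s); skipping C selection, "
                "falling back to C=1.0", minority,
            )
            self.inner_losses_ = {}
            return 1.0
        n_folds = min(self.n_inner_folds, minority)
        if n_folds < self.n_inner_folds:
            logger.warning(
                "confidence fit: minority class of %d supports only %d inner fold(s)",
                minority, n_folds,
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
        grid = sorted(float(c) for c in self.C_grid)
        losses = {C: [] for C in grid}
        self.inner_fold_sizes_ = [
            (fit.size, val.size) for fit, val in skf.split(X, y)
        ]
        for fit_idx, val_idx in skf.split(X, y):
            stats = _standardize_params(X[fit_idx]) if self.standardize else None
            Xf = self._prep(X[fit_idx], stats)
            Xv = self._prep(X[val_idx], stats)
            yv = y[val_idx]
            # one warm-started path over the C grid per fold
            lr = LogisticRegression(
                C=grid[0], solver="lbfgs", max_iter=self.max_iter,
                tol=max(self.tol, 1e-6), warm_start=True,
            )
            for C in grid:
                lr.set_params(C=C)
                lr.fit(Xf, y[fit_idx])
                z = Xv @ lr.coef_[0] + lr.intercept_[0]  # oriented to classes_[1]
                t = np.where(yv == lr.classes_[1], 1.0, -1.0)
                losses[C].append(float(np.mean(np.logaddexp(0.0, -t * z))))
        self.inner_losses_ = {C: float(np.mean(v)) for C, v in losses.items()}
        losses = self.inner_losses_
        best = min(self.C_grid)  # ties resolve to the strongest regularisation
        for C in sorted(self.C_grid):
            if losses[C] < losses[best] - 1e-15:
                best = C
        return float(best)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: np.ndarray, correct: Sequence) -> "ConfidenceEstimator":
        """Fit from a feature matrix and per-trial correctness.

        ``correct`` may be booleans (True = correct) or labels in
        {-1 confident, +1 non-confident}.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("X must be (n_trials, n_features)")
        if not np.all(np.isfinite(X)):
            raise InputError("features must be finite")
        y = self._as_labels(np.asarray(correct))
        if np.unique(y).size < 2:
            raise DegenerateTrainingError("confidence fit requires both classes")

        self.C_ = float(self.C) if self.C is not None else self._select_C(X, y)
        if self.standardize:
            self.mean_, self.scale_ = _standardize_params(X)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        lr = self._make_lr(self.C_).fit(self._prep(X, (self.mean_, self.scale_)), y)
        # sklearn orients the decision function toward classes_[1] == +1
        # (non-confident); keep that convention and negate when producing w.
        self.coef_ = lr.coef_[0].copy()
        self.intercept_ = float(lr.intercept_[0])
        self.classes_ = np.array([LABEL_CONFIDENT, LABEL_NONCONFIDENT])
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _as_labels(correct: np.ndarray) -> np.ndarray:
        if correct.dtype == bool:
            return np.where(correct, LABEL_CONFIDENT, LABEL_NONCONFIDENT)
        vals = set(np.unique(correct).tolist())
        if vals <= {LABEL_CONFIDENT, LABEL_NONCONFIDENT}:
            return correct.astype(int)
        if vals <= {0, 1}:  # treat as boolean correctness
            return np.where(correct.astype(bool), LABEL_CONFIDENT, LABEL_NONCONFIDENT)
        raise InputError(f"cannot interpret correctness labels {sorted(vals)}")

    def _score(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise InputError("features must be finite")
        Z = (X - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict_weight(self, X: np.ndarray) -> np.ndarray:
        """Confidence weight(s) ``w``: probability of the correct class.

        ``w = logistic(-score)`` because the linear score is oriented
        toward the non-confident (+1) class.
        """
        from scipy.special import expit

        return expit(-self._score(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        w = self.predict_weight(X)
        return np.column_stack([w, 1.0 - w])

    def predict(self, X: np.ndarray) -> np.ndarray:
        w = self.predict_weight(X)
        return np.where(w >= 0.5, LABEL_CONFIDENT, LABEL_NONCONFIDENT)

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "C": self.C_,
                "coef": self.coef_.tolist(),
                "intercept": self.intercept_,
                "mean": self.mean_.tolist(),
                "scale": self.scale_.tolist(),
                "label_convention": {
                    "confident": LABEL_CONFIDENT,
                    "nonconfident": LABEL_NONCONFIDENT,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceEstimator":
        payload = json.loads(text)
        model = cls(C=payload["C"])
        model.C_ = float(payload["C"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.classes_ = np.array([LABEL_CONFIDENT, LABEL_NONCONFIDENT])
        model.n_features_in_ = model.coef_.size
        return model


def fit_confidence_model(
    features: np.ndarray, correctness: Sequence, **kwargs
) -> ConfidenceEstimator:
    """Fit a :class:`ConfidenceEstimator` on per-trial features and correctness."""
    return ConfidenceEstimator(**kwargs).fit(features, correctness)


def estimate_confidence(model: ConfidenceEstimator, features: np.ndarray) -> float:
    """Confidence weight for a single feature vector."""
    return float(model.predict_weight(np.asarray(features, dtype=float)[None, :])[0])
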