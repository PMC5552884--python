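"""Common Spatial Patterns features and the per-trial feature vector.

CSP finds spatial filters ``w`` maximising the variance ratio
``w' S_a w / w' (S_a + S_b) w`` between two classes of epochs via the
generalized eigendecomposition of the class covariance matrices.  Here the
two classes are correct ("confident") and incorrect ("non-confident")
decisions, one transformation per lock type (stimulus/response), and only
the first spatial filter is used: the per-trial neural feature is the
natural log of the variance of the epoch projected onto it.

Each decision is then represented by up to three features: the
stimulus-locked log-variance, the response-locked log-variance, and the
response time in seconds.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateTrainingError, FeatureError, InputError

logger = logging.getLogger(__name__)

#: Variance floor applied before taking the log.
VAR_FLOOR = 1e-12

FeatureMode = Literal["rt_only", "nf_only", "hybrid"]


def _trial_covariances(X: np.ndarray) -> np.ndarray:
    """Per-trial channel covariance, each normalised by its trace."""
    covs = np.einsum("tcs,tds->tcd", X, X)
    traces = np.trace(covs, axis1=1, axis2=2)
    traces = np.where(traces > 0, traces, 1.0)
    return covs / traces[:, None, None]


class CSPTransformer(TransformerMixin, BaseEstimator):
    """Two-class CSP with log-variance output for the leading filter(s).

    Parameters
    ----------
    n_components : int
        Number of leading spatial filters whose log-variance is returned.
        The pipeline uses 1: only the maximum-variance-ratio pattern.
    shrinkage : float, "auto" or None
        Ridge shrinkage of the class covariances toward the identity.
        ``"auto"`` applies a small analytic amount only when the composite
        covariance is ill-conditioned; a float in [0, 1] applies that
        coefficient unconditionally; ``None`` never shrinks.
    log : bool
        If True (default) ``transform`` returns log-variances, otherwise
        raw variances.

    Attributes
    ----------
    filters_ : ndarray, (n_channels, n_channels)
        Spatial filters as rows, sorted by decreasing variance ratio for
        the first class in ``numpy.unique`` label order (with correctness
        labels -1 = confident / +1 = non-confident, this is the confident
        class).
    eigenvalues_ : ndarray, (n_channels,)
        Variance ratios in [0, 1] associated with each filter.
    covs_ : ndarray, (2, n_channels, n_channels)
        Trace-normalised class covariance estimates.
    classes_ : ndarray, (2,)
    """

    def __init__(
        self,
        n_components: int = 1,
        shrinkage: float | str | None = "auto",
        log: bool = True,
    ) -> None:
        self.n_components = n_components
        self.shrinkage = shrinkage
        self.log = log

    def fit(self, X: np.ndarray, y: Sequence) -> "CSPTransformer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise InputError("X must be (n_trials, n_channels, n_samples)")
        classes = np.unique(y)
        if classes.size != 2:
            raise DegenerateTrainingError(
                f"CSP needs exactly two classes, got {classes.tolist()}"
            )
        if min(np.sum(y == c) for c in classes) < 2:
            raise DegenerateTrainingError("CSP needs at least 2 trials per class")
        covs = _trial_covariances(X)
        s_a = covs[y == classes[0]].mean(axis=0)
        s_b = covs[y == classes[1]].mean(axis=0)
        s_a, s_b = self._shrink(s_a, s_b)
        composite = s_a + s_b
        from scipy.linalg import eigh

        evals, evecs = eigh(s_a, composite)
        order = np.argsort(evals)[::-1]
        self.classes_ = classes
        self.eigenvalues_ = np.clip(evals[order], 0.0, 1.0)
        self.filters_ = evecs[:, order].T
        self.covs_ = np.stack([s_a, s_b])
        self.n_channels_ = X.shape[1]
        return self

    def _shrink(self, s_a: np.ndarray, s_b: np.ndarray):
        gamma: float | None
        if self.shrinkage is None:
            gamma = None
        elif self.shrinkage == "auto":
            comp = s_a + s_b
            cond = np.linalg.cond(comp)
            gamma = None
            if not np.isfinite(cond) or cond > 1e10:
                gamma = 1e-6
                logger.info("CSP: composite covariance ill-conditioned (cond=%.3g); "
                            "applying shrinkage %.1e", cond, gamma)
        else:
            gamma = float(self.shrinkage)
        if gamma:
            n = s_a.shape[0]
            for s in (s_a, s_b):
                mu = np.trace(s) / n
                s *= 1.0 - gamma
                s += gamma * mu * np.eye(n)
        return s_a, s_b

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.n_channels_:
            raise InputError(
                f"X must be (n_trials, {self.n_channels_}, n_samples); got {X.shape}"
            )
        w = self.filters_[: self.n_components]
        projected = np.einsum("kc,tcs->tks", w, X)
        var = projected.var(axis=-1)
        if not self.log:
            return var
        floored = np.maximum(var, VAR_FLOOR)
        if np.any(var < VAR_FLOOR):
            logger.warning("CSP transform: %d zero-variance projection(s) floored",
                           int(np.sum(var < VAR_FLOOR)))
        return np.log(floored)


def fit_csp(epochs: np.ndarray, labels: Sequence, **kwargs) -> CSPTransformer:
    """Fit a :class:`CSPTransformer` on ``(n_trials, n_channels, n_samples)``."""
    return CSPTransformer(**kwargs).fit(epochs, labels)


def apply_csp_logvar(epoch: np.ndarray, model: CSPTransformer) -> float:
    """Log-variance of one ``(n_channels, n_samples)`` epoch under the first filter."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise InputError("epoch must be (n_channels, n_samples)")
    return float(model.transform(epoch[None])[0, 0])


def build_feature_vector(
    rt: float | None = None,
    nf_stimulus: float | None = None,
    nf_response: float | None = None,
    mode: FeatureMode = "hybrid",
) -> np.ndarray:
    """Assemble the per-trial feature vector for a weighting mode.

    ``rt_only`` -> (rt,); ``nf_only`` -> (nf_stimulus, nf_response);
    ``hybrid`` -> (nf_stimulus, nf_response, rt).
    """
    def _req(value: float | None, name: str) -> float:
        if value is None or not np.isfinite(value):
            raise FeatureError(f"feature {name!r} required for mode {mode!r}")
        return float(value)

    if mode == "rt_only":
        vec = [_req(rt, "rt")]
    elif mode == "nf_only":
        vec = [_req(nf_stimulus, "nf_stimulus"), _req(nf_response, "nf_response")]
    elif mode == "hybrid":
        vec = [
            _req(nf_stimulus, "nf_stimulus"),
            _req(nf_response, "nf_response"),
            _req(rt, "rt"),
        ]
    else:
        raise FeatureError(f"unknown feature mode {mode!r}")
    if mode != "nf_only" and vec[-1] <= 0:
        raise FeatureError("rt must be positive")
    return np.asarray(vec)


def build_feature_matrix(
    rts: np.ndarray | None,
    nf_stimulus: np.ndarray | None,
    nf_response: np.ndarray | None,
    mode: FeatureMode,
) -> np.ndarray:
    """Vectorised :func:`build_feature_vector` over aligned per-trial arrays."""
    cols: list[np.ndarray] = []
    def _req(arr, name):
        if arr is None:
            raise FeatureError(f"feature {name!r} required for mode {mode!r}")
        arr = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise FeatureError(f"feature {name!r} contains non-finite values")
        return arr

    if mode == "rt_only":
        cols = [_req(rts, "rt")]
    elif mode == "nf_only":
        cols = [_req(nf_stimulus, "nf_stimulus"), _req(nf_response, "nf_response")]
    elif mode == "hybrid":
        cols = [
            _req(nf_stimulus, "nf_stimulus"),
            _req(nf_response, "nf_response"),
            _req(rts, "rt"),
        ]
    else:
        raise FeatureError(f"unknown feature mode {mode!r}")
    return np.column_stack(cols)
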