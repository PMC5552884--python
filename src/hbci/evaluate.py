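"""Cross-validated evaluation harness for the group-decision pipeline.

Runs the full design: shared outer 10-fold cross-validation over trials
(288 train / 32 test per fold at 320 trials, stratified by stimulus class),
per-fold CSP + logistic confidence fits with no leakage into test trials,
group aggregation under every weighting method, and the statistical
contrasts used to characterise the system (Wilcoxon signed-rank method
comparisons, Kruskal-Wallis correct-vs-incorrect contrasts, per-sample ERP
contrasts, moving-average error/tie dynamics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .confidence import ConfidenceEstimator
from .exceptions import ConfigurationError, InputError
from .features import CSPTransformer, build_feature_matrix
from .groups import (
    GroupSpec,
    enumerate_groups,
    enumerate_pair_groups,
    evaluate_group_method,
    method_weights,
)
from .preprocess import EPOCH_RATE, EPOCH_SAMPLES, EpochSet, preprocess_recording
from .simulate import SimulatedSession

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def make_folds(
    n_trials: int,
    n_folds: int = 10,
    seed: int | None = None,
    stratify_by: np.ndarray | None = None,
) -> list[FoldSplit]:
    """Random near-equal partition of trials into ``n_folds`` folds.

    The same folds are shared by every participant in a run so that groups
    are always evaluated on common test trials.  When ``stratify_by`` is
    given (normally the stimulus class) folds preserve class proportions,
    so each test fold keeps ~25% targets.
    """
    if n_folds > n_trials:
        raise InputError(f"n_folds={n_folds} exceeds n_trials={n_trials}")
    from sklearn.model_selection import KFold, StratifiedKFold

    idx = np.arange(n_trials)
    if stratify_by is not None:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx, np.asarray(stratify_by))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx)
    return [
        FoldSplit(fold_index=i, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(splits)
    ]


# ---------------------------------------------------------------------------
# Statistical contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    statistic: float
    pvalue: float
    test: str
    n: tuple[int, ...] = ()


def compare_methods(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    sided: Literal["one", "two"] = "one",
) -> ContrastResult:
    """Paired Wilcoxon signed-rank comparison of per-group error rates.

    One-sided tests the alternative that ``errors_a`` are lower.  The exact
    null distribution is used for up to 25 nonzero differences, the normal
    approximation above.  All-zero differences report p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired samples must have equal length")
    diffs = a - b
    nonzero = int(np.sum(diffs != 0))
    if nonzero == 0:
        return ContrastResult(0.0, 1.0, "wilcoxon", (a.size,))
    method = "exact" if nonzero <= 25 else "approx"
    alternative = "less" if sided == "one" else "two-sided"
    res = sst.wilcoxon(a, b, alternative=alternative, method=method)
    return ContrastResult(float(res.statistic), float(res.pvalue), "wilcoxon", (a.size,))


def distribution_contrast(
    values_c: Sequence[float], values_i: Sequence[float]
) -> ContrastResult:
    """Kruskal-Wallis contrast between the correct and incorrect sets."""
    c = np.asarray(values_c, dtype=float)
    i = np.asarray(values_i, dtype=float)
    if c.size == 0 or i.size == 0:
        raise InputError("both sets must be non-empty")
    pooled = np.concatenate([c, i])
    if np.unique(pooled).size == 1 or np.array_equal(np.sort(c), np.sort(i)):
        # identical samples (or one shared value): no separation by construction
        return ContrastResult(0.0, 1.0, "kruskal", (c.size, i.size))
    h, p = sst.kruskal(c, i)
    return ContrastResult(float(h), float(p), "kruskal", (c.size, i.size))


@dataclass
class ErpContrast:
    """Grand averages and per-channel, per-sample Kruskal-Wallis p-values."""

    grand_average_correct: np.ndarray  # (n_channels, 48)
    grand_average_incorrect: np.ndarray
    statistic: np.ndarray  # (n_channels, 48)
    pvalue: np.ndarray
    channel_names: list[str] = field(default_factory=list)


def erp_contrast(
    epochs_c: np.ndarray,
    epochs_i: np.ndarray,
    channel_names: Sequence[str] | None = None,
) -> ErpContrast:
    """Correct-vs-incorrect ERP contrast on the common 48-sample grid."""
    c = np.asarray(epochs_c, dtype=float)
    i = np.asarray(epochs_i, dtype=float)
    if c.ndim != 3 or i.ndim != 3 or c.shape[1:] != i.shape[1:]:
        raise InputError("epoch sets must be (n_trials, n_channels, n_samples) and match")
    n_ch, n_s = c.shape[1:]
    stat = np.zeros((n_ch, n_s))
    pval = np.ones((n_ch, n_s))
    for ch in range(n_ch):
        for s in range(n_s):
            res = distribution_contrast(c[:, ch, s], i[:, ch, s])
            stat[ch, s] = res.statistic
            pval[ch, s] = res.pvalue
    return ErpContrast(
        grand_average_correct=c.mean(axis=0),
        grand_average_incorrect=i.mean(axis=0),
        statistic=stat,
        pvalue=pval,
        channel_names=list(channel_names) if channel_names is not None else [],
    )


def latency_to_sample(latency_ms: float, lock: Literal["stimulus", "response"]) -> int:
    """Map a latency to a sample index on the conditioned 48-sample grid.

    Stimulus-locked epochs span [0, 1500) ms after stimulus onset;
    response-locked epochs span [-1000, 500) ms around the response.
    """
    t0 = 0.0 if lock == "stimulus" else -1000.0
    idx = int(np.floor((latency_ms - t0) * EPOCH_RATE / 1000.0))
    if not 0 <= idx < EPOCH_SAMPLES:
        raise InputError(f"latency {latency_ms} ms outside the {lock}-locked epoch")
    return idx


@dataclass
class MovingAverageResult:
    series: np.ndarray
    slope: float
    intercept: float
    correlation: float
    pvalue: float


def moving_average_error(
    flags: Sequence[float], window: int = 40
) -> MovingAverageResult:
    """Moving-average smoothing of a 0/1 error (or tie) indicator plus trend.

    Overlapping windows advance one trial at a time; an ordinary
    least-squares line is fit to the smoothed series and reported with its
    correlation coefficient and two-sided p-value.
    """
    x = np.asarray(flags, dtype=float)
    if window < 1 or window > x.size:
        raise InputError(f"window={window} invalid for series of {x.size}")
    series = np.convolve(x, np.ones(window) / window, mode="valid")
    if series.size < 2 or np.allclose(series, series[0]):
        return MovingAverageResult(series, 0.0, float(series.mean()), 0.0, 1.0)
    t = np.arange(series.size, dtype=float)
    fit = sst.linregress(t, series)
    return MovingAverageResult(
        series, float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)
    )


# ---------------------------------------------------------------------------
# End-to-end cross-validated run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outputs of a full cross-validated cohort evaluation."""

    table: pd.DataFrame  # method, size, group, error_rate, tie_count
    weights: dict[str, np.ndarray]  # feature mode -> (n_participants, n_trials)
    decisions: np.ndarray  # (n_participants, n_trials) first responses
    second_decisions: np.ndarray
    reported_confidence: np.ndarray
    correct: np.ndarray  # (n_participants, n_trials) booleans
    truth: np.ndarray  # (n_trials,)
    folds: list[FoldSplit]
    trial_indices: np.ndarray
    epoch_sets: list[EpochSet] = field(repr=False, default_factory=list)


_METHOD_MODES = {"rtci": "rt_only", "nf_bci": "nf_only", "hbci": "hybrid"}


def estimate_cv_weights(
    stim_epochs: np.ndarray,
    resp_epochs: np.ndarray,
    rts: np.ndarray,
    correct: np.ndarray,
    folds: Sequence[FoldSplit],
    modes: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-trial confidence weights for one participant, one mode each.

    For every outer fold, CSP (one transformation per lock type) and the
    logistic confidence model are fit on the fold's training trials only;
    weights are predicted for the fold's test trials.  Concatenated over
    folds this covers every trial exactly once.  A fold whose training
    labels are single-class falls back to constant weight 1 (logged).
    """
    n_trials = rts.size
    out = {mode: np.ones(n_trials) for mode in modes}
    labels = np.where(correct, -1, 1)
    for fold in folds:
        tr, te = fold.train_indices, fold.test_indices
        if np.unique(labels[tr]).size < 2 or min(
            np.sum(labels[tr] == -1), np.sum(labels[tr] == 1)
        ) < 2:
            logger.warning(
                "fold %d: degenerate correctness labels; constant weight 1 fallback",
                fold.fold_index,
            )
            continue
        nf = {}
        if any(m in ("nf_only", "hybrid") for m in modes):
            csp_s = CSPTransformer().fit(stim_epochs[tr], labels[tr])
            csp_r = CSPTransformer().fit(resp_epochs[tr], labels[tr])
            nf["s_tr"] = csp_s.transform(stim_epochs[tr])[:, 0]
            nf["s_te"] = csp_s.transform(stim_epochs[te])[:, 0]
            nf["r_tr"] = csp_r.transform(resp_epochs[tr])[:, 0]
            nf["r_te"] = csp_r.transform(resp_epochs[te])[:, 0]
        for mode in modes:
            X_tr = build_feature_matrix(
                rts[tr], nf.get("s_tr"), nf.get("r_tr"), mode
            )
            X_te = build_feature_matrix(
                rts[te], nf.get("s_te"), nf.get("r_te"), mode
            )
            model = ConfidenceEstimator().fit(X_tr, correct[tr])
            out[mode][te] = model.predict_weight(X_te)
    return out


def run_pipeline_cv(
    sessions: Sequence[SimulatedSession],
    methods: Sequence[str] = ("majority", "hbci"),
    sizes: Sequence[int] = tuple(range(1, 11)),
    n_folds: int = 10,
    seed: int = 0,
    enumeration: Literal["all_subsets", "pair_preserving"] = "all_subsets",
    keep_epochs: bool = False,
) -> RunResult:
    """Full evaluation of a cohort: preprocess, cross-validate, aggregate.

    ``sizes`` are group sizes under ``all_subsets`` enumeration; under
    ``pair_preserving`` they must be even and are built from whole pairs
    ``(0,1), (2,3), ...``.  Trials excluded during epoching for any
    participant are dropped from the common trial set.
    """
    modes = sorted({_METHOD_MODES[m] for m in methods if m in _METHOD_MODES})
    for m in methods:
        if m not in ("majority", "confidence_majority", "second_response_majority") and m not in _METHOD_MODES:
            raise ConfigurationError(f"unknown method {m!r}")

    epoch_sets = [preprocess_recording(s.recording) for s in sessions]
    common = epoch_sets[0].trial_indices
    for es in epoch_sets[1:]:
        common = np.intersect1d(common, es.trial_indices)
    n_all = len(sessions[0].trials)
    if common.size < n_all:
        logger.info("dropping %d trial(s) excluded during epoching", n_all - common.size)

    trials0 = sessions[0].trials
    truth = np.where(trials0["is_target"].to_numpy()[common], 1, -1)
    folds = make_folds(
        common.size, n_folds=n_folds, seed=seed,
        stratify_by=trials0["is_target"].to_numpy()[common],
    )

    n_p = len(sessions)
    decisions = np.empty((n_p, common.size), dtype=int)
    second = np.empty((n_p, common.size), dtype=int)
    reported = np.empty((n_p, common.size))
    correct = np.empty((n_p, common.size), dtype=bool)
    weights = {mode: np.ones((n_p, common.size)) for mode in modes}
    for p, (session, es) in enumerate(zip(sessions, epoch_sets)):
        t = session.trials
        sel = common
        decisions[p] = t["decision"].to_numpy()[sel]
        second[p] = t["second_response"].to_numpy()[sel]
        reported[p] = t["reported_confidence"].to_numpy()[sel]
        correct[p] = t["correct"].to_numpy()[sel]
        if modes:
            pos = np.searchsorted(es.trial_indices, sel)
            w = estimate_cv_weights(
                es.stimulus[pos], es.response[pos],
                t["rt"].to_numpy()[sel], correct[p], folds, modes,
            )
            for mode in modes:
                weights[mode][p] = w[mode]

    rng = np.random.default_rng(seed)
    frames = []
    for method in methods:
        d = second if method == "second_response_majority" else decisions
        w = method_weights(
            method, n_p, common.size,
            model_weights=weights, reported_confidence=reported,
        )
        for size in sizes:
            if enumeration == "pair_preserving":
                if size % 2:
                    raise ConfigurationError("pair-preserving groups must have even size")
                pairs = [(i, i + 1) for i in range(0, n_p, 2)]
                groups: list[GroupSpec] = enumerate_pair_groups(pairs, size // 2)
            else:
                groups = enumerate_groups(n_p, size)
            res = evaluate_group_method(groups, d, w, truth, rng, method=method)
            frames.append(res.to_frame())

    return RunResult(
        table=pd.concat(frames, ignore_index=True),
        weights=weights,
        decisions=decisions,
        second_decisions=second,
        reported_confidence=reported,
        correct=correct,
        truth=truth,
        folds=folds,
        trial_indices=common,
        epoch_sets=epoch_sets if keep_epochs else [],
    )


def replication_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    sizes: tuple[int, ...] = (2, 4),
    n_participants: int = 10,
    n_channels: int = 16,
    sampling_rate: float = 128.0,
    communication: bool = False,
) -> pd.DataFrame:
    """Repeat the full simulate-and-evaluate pipeline across seeds.

    For every seed: generate a cohort, run the cross-validated pipeline
    with the hybrid and plain-majority methods, and record per group size
    the one-sided signed-rank p-value for "hybrid groups err less than
    majority groups" together with mean error rates, plus the
    Kruskal-Wallis p-value contrasting estimated confidence between
    correct and incorrect trials.  Returns one row per seed.
    """
    from .simulate import SimulationConfig, simulate_cohort

    rows = []
    for i in range(n_seeds):
        seed = int((base_seed * 100_003 + i) % (2**31 - 1))
        config = SimulationConfig(
            n_participants=n_participants,
            n_channels=n_channels,
            sampling_rate=sampling_rate,
            communication_mode=communication,
            seed=seed,
        )
        sessions = simulate_cohort(config)
        res = run_pipeline_cv(
            sessions,
            methods=("majority", "hbci"),
            sizes=sizes,
            seed=seed,
            enumeration="pair_preserving" if communication else "all_subsets",
        )
        t = res.table
        row: dict[str, float] = {"seed": seed}
        for size in sizes:
            a = t[(t["method"] == "hbci") & (t["size"] == size)]["error_rate"].to_numpy()
            b = t[(t["method"] == "majority") & (t["size"] == size)]["error_rate"].to_numpy()
            row[f"p_size{size}"] = compare_methods(a, b, sided="one").pvalue
            row[f"hbci_err_size{size}"] = float(a.mean())
            row[f"majority_err_size{size}"] = float(b.mean())
        w = res.weights["hybrid"]
        row["individual_err"] = float((res.decisions != res.truth).mean())
        row["w_contrast_p"] = distribution_contrast(
            w[res.correct], w[~res.correct]
        ).pvalue
        rows.append(row)
    return pd.DataFrame(rows)
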