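"""Confidence-weighted majority aggregation of individual decisions.

For trial ``i`` a group of ``m`` members decides
``G_i = sign(sum_p w_{p,i} * d_{p,i})`` with ``d`` in {-1, +1} and
nonnegative weights ``w``.  An exactly zero sum is a tie, resolved by a
uniform random draw between +1 and -1 from a supplied generator (draw order
fixed by group index, then trial index, so runs are bit-reproducible).

Two enumeration schemes are supported: all ``C(n, m)`` subsets of ``n``
participants, and pair-preserving groups built as unions of whole
communicating pairs (never splitting a pair; only even sizes exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

#: The weighting methods; weights come per method from constant 1s
#: (majority), the RT-only / neural-only / hybrid logistic models, reported
#: confidence on the raw 0-100 scale, or constant 1s over second responses.
METHODS: tuple[str, ...] = (
    "majority",
    "rtci",
    "nf_bci",
    "hbci",
    "confidence_majority",
    "second_response_majority",
)


@dataclass(frozen=True)
class GroupSpec:
    """A group: member indices plus the enumeration scheme that formed it."""

    members: tuple[int, ...]
    scheme: Literal["all_subsets", "pair_preserving"] = "all_subsets"

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise InputError("group members must be distinct")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GroupDecisionRecord:
    """Outcome of the weighted majority rule on one trial."""

    trial_index: int
    decision: int
    member_decisions: np.ndarray
    member_weights: np.ndarray
    tie: bool = False


def weighted_group_decision(
    decisions: Sequence[int],
    weights: Sequence[float],
    rng: np.random.Generator,
    trial_index: int = 0,
) -> GroupDecisionRecord:
    """Apply the weighted majority rule to one trial.

    ``G = sign(sum w*d)``; an exact zero sum is broken by a uniform random
    choice between +1 and -1 drawn from ``rng``.
    """
    d = np.asarray(decisions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.size == 0:
        raise InputError("empty group")
    if d.shape != w.shape:
        raise InputError("decisions and weights must have equal length")
    if not np.all(np.isin(d, (-1.0, 1.0))):
        raise InputError("decisions must be +1 or -1")
    if np.any(w < 0):
        raise InputError("weights must be nonnegative")
    total = float(w @ d)
    # scale-relative tolerance: equal weights must cancel to a tie even when
    # floating-point summation leaves dust
    tie = abs(total) <= 1e-9 * (w.max() if w.size else 0.0)
    if tie:
        g = int(rng.integers(0, 2)) * 2 - 1
    else:
        g = 1 if total > 0 else -1
    return GroupDecisionRecord(
        trial_index=trial_index,
        decision=g,
        member_decisions=d.astype(int),
        member_weights=w,
        tie=tie,
    )


def enumerate_groups(n: int, m: int) -> list[GroupSpec]:
    """All ``C(n, m)`` subsets of ``range(n)``, lexicographic order."""
    if not 1 <= m <= n:
        raise InputError(f"need 1 <= m <= n, got m={m}, n={n}")
    return [GroupSpec(members=c) for c in combinations(range(n), m)]


def enumerate_pair_groups(
    pairs: Sequence[tuple[int, int]], k: int
) -> list[GroupSpec]:
    """All ``C(#pairs, k)`` groups of size ``2k`` built from whole pairs."""
    if not 1 <= k <= len(pairs):
        raise InputError(f"need 1 <= k <= {len(pairs)}, got k={k}")
    for pair in pairs:
        if len(pair) != 2:
            raise InputError("each pair must have exactly two members")
    out = []
    for combo in combinations(range(len(pairs)), k):
        members = tuple(p for idx in combo for p in pairs[idx])
        out.append(GroupSpec(members=members, scheme="pair_preserving"))
    return out


@dataclass
class GroupMethodResult:
    """Per-group error rates (and tie counts) for one method."""

    method: str
    groups: list[GroupSpec]
    error_rates: np.ndarray  # (n_groups,)
    tie_counts: np.ndarray  # (n_groups,)
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "size": [g.size for g in self.groups],
                "group": ["+".join(map(str, g.members)) for g in self.groups],
                "error_rate": self.error_rates,
                "tie_count": self.tie_counts,
            }
        )


def evaluate_group_method(
    groups: Sequence[GroupSpec],
    decisions: np.ndarray,
    weights: np.ndarray,
    truth: np.ndarray,
    rng: np.random.Generator,
    method: str = "majority",
) -> GroupMethodResult:
    """Error rate of every group under one weighting method.

    ``decisions`` and ``weights`` are ``(n_participants, n_trials)``
    aligned matrices, ``truth`` the ``(n_trials,)`` correct answers in
    {-1, +1}.  Ties are broken with ``rng``; draws occur in (group, trial)
    order over tied trials only, so a fixed seed reproduces the run.
    """
    decisions = np.asarray(decisions)
    weights = np.asarray(weights, dtype=float)
    truth = np.asarray(truth)
    if decisions.shape != weights.shape:
        raise ConfigurationError("decisions and weights must have matching shapes")
    if decisions.shape[1] != truth.size:
        raise ConfigurationError("truth length must match trial count")
    if np.any(weights < 0):
        raise InputError("weights must be nonnegative")
    n_trials = truth.size
    error_rates = np.empty(len(groups))
    tie_counts = np.empty(len(groups), dtype=int)
    for gi, group in enumerate(groups):
        members = list(group.members)
        totals = np.einsum("pt,pt->t", weights[members], decisions[members])
        g = np.sign(totals)
        w_max = weights[members].max() if weights[members].size else 0.0
        ties = np.abs(totals) <= 1e-9 * w_max
        if np.any(ties):
            g[ties] = rng.integers(0, 2, size=int(ties.sum())) * 2 - 1
        error_rates[gi] = np.mean(g != truth)
        tie_counts[gi] = int(ties.sum())
    return GroupMethodResult(
        method=method,
        groups=list(groups),
        error_rates=error_rates,
        tie_counts=tie_counts,
        n_trials=n_trials,
    )


def method_weights(
    method: str,
    n_participants: int,
    n_trials: int,
    model_weights: Mapping[str, np.ndarray] | None = None,
    reported_confidence: np.ndarray | None = None,
) -> np.ndarray:
    """Weight matrix for a named method.

    ``model_weights`` maps feature mode ("rt_only"/"nf_only"/"hybrid") to
    estimated ``(n_participants, n_trials)`` confidence weights; reported
    confidence is used raw on its 0-100 scale, so a reported 0 abstains.
    """
    ones = np.ones((n_participants, n_trials))
    if method in ("majority", "second_response_majority"):
        return ones
    if method == "confidence_majority":
        if reported_confidence is None:
            raise ConfigurationError("confidence_majority requires reported confidences")
        return np.asarray(reported_confidence, dtype=float)
    mode = {"rtci": "rt_only", "nf_bci": "nf_only", "hbci": "hybrid"}.get(method)
    if mode is None:
        raise ConfigurationError(f"unknown method {method!r}")
    if model_weights is None or mode not in model_weights:
        raise ConfigurationError(f"method {method!r} requires estimated {mode} weights")
    return np.asarray(model_weights[mode], dtype=float)
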