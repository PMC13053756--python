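"""Association statistics used to build and test epigenomic prior networks.

The central quantities are Somers' D (a concordance statistic between a
continuous score and a binary label, related to the ROC area by
``AUC = (D + 1) / 2``), the Spearman rank correlation, and a Fisher
z-transform significance test applied to either.  The same
``sqrt(R - 3)`` variance scaling is used for both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._exceptions import UndefinedStatisticError, ValidationError

__all__ = [
    "ConcordanceStat",
    "FisherZResult",
    "somers_d",
    "spearman_rho",
    "fisher_z_test",
    "bh_adjust",
    "proportions_ztest",
]


@dataclass(frozen=True)
class ConcordanceStat:
    """Somers' D with its AUC transform ``AUC = (D + 1) / 2``."""

    d: float
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float
    infinite: bool = False


def somers_d(score, label) -> ConcordanceStat:
    """Somers' D of a continuous score against a binary label.

    ``D = (concordant - discordant) / (n1 * n0)`` over all cross-class
    pairs; tied scores contribute 0.  Computed via mid-rank sums (the
    Mann-Whitney identity), which agrees exactly with pairwise
    enumeration.

    Raises
    ------
    UndefinedStatisticError
        If only one class is present in ``label``.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    if score.shape != label.shape or score.ndim != 1:
        raise ValidationError("score and label must be 1-D of equal length")
    if len(score) < 2:
        raise ValidationError("need at least 2 observations")
    uniq = np.unique(label)
    if not np.isin(uniq, (0, 1)).all():
        raise ValidationError("label must be binary (0/1)")
    n1 = int((label == 1).sum())
    n0 = int((label == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError(
            "Somers' D undefined: only one class present"
        )
    ranks = sps.rankdata(score)  # mid-ranks for ties
    auc = (ranks[label == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    d = 2.0 * auc - 1.0
    return ConcordanceStat(d=float(d), auc=float(auc), n_pos=n1, n_neg=n0)


def spearman_rho(score, value) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Raises
    ------
    UndefinedStatisticError
        If either vector is constant (rank correlation undefined).
    """
    score = np.asarray(score, dtype=float)
    value = np.asarray(value, dtype=float)
    if score.shape != value.shape or score.ndim != 1:
        raise ValidationError("inputs must be 1-D of equal length")
    if len(score) < 3:
        raise ValidationError("need at least 3 observations")
    if not (np.isfinite(score).all() and np.isfinite(value).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(score) == 0 or np.ptp(value) == 0:
        raise UndefinedStatisticError(
            "Spearman correlation undefined for a constant vector"
        )
    rho = sps.spearmanr(score, value).statistic
    return float(rho)


def fisher_z_test(stat: float, r_used: int) -> FisherZResult:
    """Fisher-transform z-test for a correlation-type statistic.

    ``z = atanh(stat) * sqrt(R - 3)`` with a two-sided standard-normal
    p-value.  ``|stat| = 1`` maps to an infinite z, reported as p = 0
    with ``infinite=True``.
    """
    if r_used < 4:
        raise ValidationError("fisher_z_test requires R_used >= 4")
    if not np.isfinite(stat) or abs(stat) > 1:
        raise ValidationError("statistic must lie in [-1, 1]")
    if abs(stat) == 1.0:
        z = np.inf if stat > 0 else -np.inf
        return FisherZResult(z=float(z), p=0.0, infinite=True)
    z = np.arctanh(stat) * np.sqrt(r_used - 3)
    p = 2.0 * sps.norm.sf(abs(z))
    return FisherZResult(z=float(z), p=float(p), infinite=False)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def proportions_ztest(k_a: int, n_a: int, k_b: int, n_b: int) -> tuple[float, float]:
    """Two-sample z-test of proportions with pooled variance.

    Returns ``(z, p)`` with a two-sided p-value.

    Raises
    ------
    UndefinedStatisticError
        If the pooled proportion is 0 or 1 (zero pooled variance).
    """
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n < 1 or not (0 <= k <= n):
            raise ValidationError("require 0 <= k <= n and n >= 1")
    pooled = (k_a + k_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        raise UndefinedStatisticError(
            "pooled proportion is 0 or 1; z undefined"
        )
    se = np.sqrt(pooled * (1 - pooled) * (1.0 / n_a + 1.0 / n_b))
    z = (k_a / n_a - k_b / n_b) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
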