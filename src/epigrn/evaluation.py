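"""Benchmarking and validation of inferred networks.

* :func:`grn_auc` — rank-based AUC of edge scores against a known
  ground-truth network.
* :func:`ablation_zscore` / :func:`ablation_study` — does the
  target-specific prior add information?  The observed R-squared of a
  linear model on the selected regulators is standardized against a
  null built by re-running the identical select-then-fit procedure on
  random candidate sets drawn from the whole prior.
* :func:`overlap_odds_ratio` — Fisher's exact test of the overlap of
  two edge sets over a common universe, with a Woolf-logit 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import UndefinedStatisticError, ValidationError
from .grn import ThresholdTable, fit_target_model
from .io import ExpressionMatrix
from .prior import PriorNetwork
from .simulate import GroundTruthNetwork

__all__ = [
    "AblationRecord",
    "grn_auc",
    "ablation_zscore",
    "ablation_study",
    "overlap_odds_ratio",
]


def grn_auc(
    gains: pd.DataFrame | dict,
    truth: GroundTruthNetwork | set,
    candidate_universe=None,
) -> float:
    """Rank-based AUC of gain scores for true vs non-true edges.

    ``gains`` maps candidate edges (tf, target) to scores (a dict, or a
    DataFrame with tf_id/target_id/weight columns).  The candidate
    universe defaults to the scored edges; every true edge must lie in
    the universe.  Ties are handled by mid-ranks.
    """
    if isinstance(gains, pd.DataFrame):
        gains = {
            (r.tf_id, r.target_id): float(r.weight)
            for r in gains.itertuples()
        }
    truth_edges = truth.edge_set() if isinstance(truth, GroundTruthNetwork) \
        else set(truth)
    universe = set(candidate_universe) if candidate_universe is not None \
        else set(gains)
    missing = truth_edges - universe
    if missing:
        raise ValidationError(
            f"true edges outside the candidate universe: {sorted(missing)[:5]}"
        )
    scores = np.array([gains.get(e, 0.0) for e in sorted(universe)])
    labels = np.array([e in truth_edges for e in sorted(universe)])
    if labels.all() or not labels.any():
        raise UndefinedStatisticError("universe contains a single class")
    ranks = sps.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class AblationRecord:
    """Observed vs null R-squared for one target gene."""

    target_id: str
    r2_obs: float
    null_mean: float
    null_sd: float
    z: float
    n_randomizations: int
    p: int                      # candidate count used for null draws
    q: int                      # regulators selected for the observed fit


def _linear_r2(target: str, regulators, expr: ExpressionMatrix) -> float:
    """R-squared of an OLS fit (intercept + regulators) on all samples."""
    y = expr.values.loc[target].to_numpy(dtype=float)
    if not regulators:
        return 0.0
    X = expr.values.loc[sorted(regulators)].to_numpy(dtype=float).T
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(max(0.0, 1.0 - (resid ** 2).sum() / ss_tot))


def _select_then_r2(
    target: str,
    candidates,
    expr: ExpressionMatrix,
    threshold: float,
    hyper: dict | None,
    seed: int,
) -> float:
    fit = fit_target_model(
        target, candidates, expr, hyper=hyper, seed=seed, threshold=threshold
    )
    return _linear_r2(target, fit.selected, expr)


def ablation_zscore(
    target: str,
    prior: PriorNetwork,
    expr: ExpressionMatrix,
    n_rand: int = 100,
    thresholds: ThresholdTable | None = None,
    threshold: float | None = None,
    hyper: dict | None = None,
    seed: int = 0,
) -> AblationRecord:
    """Standardize a target's selected-regulator R-squared against a null.

    The observed statistic applies select-then-linear-fit to the
    target's prior candidates.  The null repeats the identical
    procedure ``n_rand`` times on p TFs drawn uniformly without
    replacement from all TFs in the prior (excluding the target).
    """
    if n_rand < 2:
        raise ValidationError("n_rand must be >= 2")
    if target not in prior.parents:
        raise ValidationError(f"{target!r} is not a prior target")
    genes = set(expr.gene_ids)
    cands = sorted((prior.parents[target] & genes) - {target})
    if not cands:
        raise ValidationError(f"no expressed candidates for {target!r}")
    p = len(cands)
    n = expr.n_samples
    if threshold is None:
        threshold = thresholds.lookup(n, p) if thresholds is not None else 0.0

    rng = np.random.default_rng([seed, 4])
    fit = fit_target_model(
        target, cands, expr, hyper=hyper, seed=seed, threshold=threshold
    )
    r2_obs = _linear_r2(target, fit.selected, expr)

    pool = sorted((set(prior.tfs) & genes) - {target})
    if len(pool) < 1:
        raise ValidationError("no TFs available for the null pool")
    k = min(p, len(pool))
    null = np.empty(n_rand)
    for b in range(n_rand):
        draw = sorted(rng.choice(pool, size=k, replace=False))
        null[b] = _select_then_r2(
            target, draw, expr, threshold, hyper, seed=seed + 1 + b
        )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise UndefinedStatisticError("null R2 distribution has zero spread")
    z = (r2_obs - null_mean) / null_sd
    return AblationRecord(
        target_id=target, r2_obs=r2_obs, null_mean=null_mean,
        null_sd=null_sd, z=float(z), n_randomizations=n_rand,
        p=p, q=fit.q,
    )


def ablation_study(
    prior: PriorNetwork,
    expr: ExpressionMatrix,
    targets=None,
    n_rand: int = 100,
    thresholds: ThresholdTable | None = None,
    threshold: float | None = None,
    hyper: dict | None = None,
    seed: int = 0,
) -> tuple[list[AblationRecord], float, float]:
    """Ablation z-scores over targets plus a one-sided t-test (z > 0)."""
    genes = set(expr.gene_ids)
    if targets is None:
        targets = [t for t in prior.targets if t in genes]
    records = []
    for i, target in enumerate(targets):
        try:
            rec = ablation_zscore(
                target, prior, expr, n_rand=n_rand, thresholds=thresholds,
                threshold=threshold, hyper=hyper,
                seed=(seed * 99991 + i) % (2**31),
            )
        except (UndefinedStatisticError, ValidationError):
            continue
        records.append(rec)
    if len(records) < 2:
        raise ValidationError("need at least 2 targets with defined z")
    zs = np.array([r.z for r in records])
    t_res = sps.ttest_1samp(zs, 0.0, alternative="greater")
    return records, float(t_res.statistic), float(t_res.pvalue)


def overlap_odds_ratio(
    set_a,
    set_b,
    universe,
) -> tuple[float, tuple[float, float], float, bool]:
    """Odds ratio, Woolf 95% CI and Fisher's exact p for set overlap.

    The 2x2 table classifies every universe element by membership in A
    and B.  A zero cell triggers the Haldane 0.5 correction for the OR
    and CI (flagged by the returned boolean); the exact p-value always
    uses the uncorrected table.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("A and B must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe - set_a - set_b)
    table = np.array([[a, b], [c, d]], dtype=float)
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    lo = float(np.exp(np.log(odds) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(odds) + 1.959963984540054 * se))
    p = float(sps.fisher_exact(table.astype(int), alternative="two-sided")[1])
    return float(odds), (lo, hi), p, bool(corrected)
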