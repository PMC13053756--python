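"""Differential regulation between two conditions.

For every TF, the importance gains it receives across its shared prior
targets in two condition-specific GRN fits are compared with a paired
t-test; Benjamini-Hochberg adjustment controls the FDR across TFs.
Candidates fitted but never split on contribute gain 0, keeping the
paired sample complete.  A differential network assembles the
significant TFs with their differentially expressed targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import ValidationError
from .grn import GRNResults, TargetFit
from .prior import PriorNetwork
from .stats import bh_adjust, proportions_ztest  # re-exported surface

__all__ = [
    "DiffRegTable",
    "DiffNetwork",
    "diff_reg_test",
    "build_differential_network",
    "bh_adjust",
    "proportions_ztest",
]


@dataclass
class DiffRegTable:
    """Per-TF differential-regulation test results.

    ``df`` columns: tf_id, n_shared_targets, mean_diff, t, p, fdr,
    direction ('hyper' = stronger regulation in condition A).
    """

    df: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def significant(self, fdr_threshold: float = 0.05) -> pd.DataFrame:
        return self.df[self.df["fdr"] < fdr_threshold].reset_index(drop=True)


def _fits_by_target(fits) -> dict[str, TargetFit]:
    if isinstance(fits, GRNResults):
        return dict(fits.target_fits)
    if isinstance(fits, Mapping):
        return dict(fits)
    return {f.target_id: f for f in fits}


def diff_reg_test(
    fits_a,
    fits_b,
    prior: PriorNetwork,
    fdr_threshold: float = 0.05,
) -> DiffRegTable:
    """Paired t-test of per-target importance gains, condition A vs B.

    For each TF, the paired sample runs over the prior targets of that
    TF fitted in both conditions; TFs with fewer than 2 shared targets
    are excluded (listed in ``excluded``).  Gains enter the test on the
    log1p scale: importance gains are heavy-tailed across targets
    (their scale follows the target's expression variance), and the
    paired t-statistic is poorly calibrated on the raw scale; log1p
    keeps unused candidates at exactly 0 and preserves direction.
    ``mean_diff`` is the mean paired difference on the log1p scale.
    """
    fa = _fits_by_target(fits_a)
    fb = _fits_by_target(fits_b)
    tf_targets: dict[str, list[str]] = {}
    for target, tfs in prior.parents.items():
        if target in fa and target in fb:
            for tf in tfs:
                tf_targets.setdefault(tf, []).append(target)

    rows = []
    excluded = []
    for tf in sorted(tf_targets):
        shared = [
            t for t in tf_targets[tf]
            if tf in fa[t].gain and tf in fb[t].gain
        ]
        if len(shared) < 2:
            excluded.append(tf)
            continue
        ga = np.log1p([fa[t].gain[tf] for t in shared])
        gb = np.log1p([fb[t].gain[tf] for t in shared])
        mean_diff = float((ga - gb).mean())
        if np.ptp(ga - gb) == 0:
            # identical gains in both conditions: no evidence either way
            t_stat, p = 0.0, 1.0
        else:
            res = sps.ttest_rel(ga, gb)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append((
            tf, len(shared), mean_diff, t_stat, p,
            "hyper" if mean_diff > 0 else "hypo",
        ))
    df = pd.DataFrame(
        rows,
        columns=["tf_id", "n_shared_targets", "mean_diff", "t", "p",
                 "direction"],
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    df = df[["tf_id", "n_shared_targets", "mean_diff", "t", "p", "fdr",
             "direction"]]
    return DiffRegTable(df=df, excluded=excluded)


@dataclass
class DiffNetwork:
    """Differential-regulation network: significant TFs (large nodes),
    DE target genes (small nodes), and the selected GRN edges between
    them, per condition."""

    nodes: pd.DataFrame   # node_id, role ('tf'|'target'), label
    edges: pd.DataFrame   # tf_id, target_id, condition, weight

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_differential_network(
    diff: DiffRegTable,
    de_labels: Mapping[str, str] | pd.Series,
    grn_a: GRNResults,
    grn_b: GRNResults,
    fdr_threshold: float = 0.05,
) -> DiffNetwork:
    """Assemble the network of significant TFs and their DE targets.

    ``de_labels`` maps genes to 'up' / 'down' / 'ns'; genes not listed
    default to 'ns'.  Edges are the selected GRN edges from either
    condition between an included TF and an included target.
    """
    if isinstance(de_labels, pd.Series):
        de_labels = de_labels.to_dict()
    sig = diff.significant(fdr_threshold)
    sig_tfs = set(sig["tf_id"])
    direction = dict(zip(sig["tf_id"], sig["direction"]))

    edge_rows = []
    target_nodes: set[str] = set()
    for cond, grn in (("A", grn_a), ("B", grn_b)):
        sel = grn.selected_edges
        for row in sel.itertuples():
            if row.tf_id not in sig_tfs:
                continue
            label = de_labels.get(row.target_id, "ns")
            if label == "ns":
                continue
            edge_rows.append((row.tf_id, row.target_id, cond, row.weight))
            target_nodes.add(row.target_id)

    node_rows = [
        (tf, "tf", direction[tf]) for tf in sorted(sig_tfs)
    ] + [
        (t, "target", de_labels.get(t, "ns")) for t in sorted(target_nodes)
    ]
    nodes = pd.DataFrame(node_rows, columns=["node_id", "role", "label"])
    edges = pd.DataFrame(
        edge_rows, columns=["tf_id", "target_id", "condition", "weight"]
    )
    return DiffNetwork(nodes=nodes, edges=edges)
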