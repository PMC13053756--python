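"""Synthetic data generators.

Everything the inference pipeline consumes can be simulated here:

* a signed, acyclic ground-truth TF->gene network;
* steady-state kinetic expression profiles (Hill activation/repression
  evaluated in topological order, multiplicative lognormal cell noise,
  Poisson counts at a configured library depth) — a deliberately
  simplified stand-in for full stochastic reaction-kinetics simulators;
* decoy-augmented prior networks (true parents plus random non-parent
  TFs);
* motif-ranking/epigenomic-signal matrices with planted TF-activity
  associations, for exercising the prior-network constructors.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._exceptions import ValidationError
from .io import (
    ExpressionMatrix,
    MotifRankingMatrix,
    RegionSet,
    RegionSignalMatrix,
    TssTable,
)
from .prior import PriorNetwork, assign_regions_to_genes, matched_regions

__all__ = [
    "SimulationSpec",
    "GroundTruthNetwork",
    "EpigenomeSim",
    "simulate_network",
    "simulate_expression",
    "simulate_prior",
    "simulate_epigenome",
]


@dataclass
class SimulationSpec:
    """Parameters of the kinetic ground-truth simulation.

    Defaults emulate the benchmark conditions used throughout the
    package's tests: a network of ~100 genes observed in 300
    high-depth expression profiles.
    """

    n_tf: int = 20
    n_targets: int = 80
    mean_in_degree: float = 2.0     # Poisson mean for parents per gene
    activation_fraction: float = 0.75
    hill: float = 2.0               # Hill coefficient h
    k_half: float = 1.0             # half-saturation K
    production: float = 2.0         # production rate v
    degradation: float = 1.0        # degradation rate lambda
    noise_sd: float = 0.3           # lognormal cell-noise sd (log scale)
    root_log_mean: float = 0.5      # lognormal baseline for root TFs
    root_log_sd: float = 0.8
    library_depth: int = 1_000_000  # expected reads per cell
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hill", "k_half", "production", "degradation"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.activation_fraction <= 1):
            raise ValidationError("activation_fraction must lie in [0, 1]")
        if self.n_tf < 2 or self.n_targets < 1:
            raise ValidationError("need n_tf >= 2 and n_targets >= 1")
        if self.mean_in_degree <= 0:
            raise ValidationError("mean_in_degree must be > 0")


@dataclass
class GroundTruthNetwork:
    """Signed, acyclic regulatory network used for benchmarking.

    ``edges`` has columns tf_id, target_id, sign (+1 activator, -1
    repressor); ``order`` lists all genes in topological order.
    """

    edges: pd.DataFrame
    tf_ids: list[str]
    target_ids: list[str]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.edges["tf_id"] == self.edges["target_id"]).any():
            raise ValidationError("self-edges are not allowed")
        if self.edges.duplicated(["tf_id", "target_id"]).any():
            raise ValidationError("duplicate edges")
        if not self.order:
            self.order = list(self.tf_ids) + list(self.target_ids)
        pos = {g: i for i, g in enumerate(self.order)}
        for row in self.edges.itertuples():
            if pos[row.tf_id] >= pos[row.target_id]:
                raise ValidationError("edges must respect topological order")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.order)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents_of(self, gene: str) -> list[str]:
        sub = self.edges[self.edges["target_id"] == gene]
        return sub["tf_id"].tolist()

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            (r.tf_id, r.target_id) for r in self.edges.itertuples()
        }


def simulate_network(spec: SimulationSpec) -> GroundTruthNetwork:
    """Draw a signed DAG: each gene samples parents from earlier TFs."""
    rng = np.random.default_rng([spec.seed, 0])
    tfs = [f"TF{i + 1}" for i in range(spec.n_tf)]
    targets = [f"G{i + 1}" for i in range(spec.n_targets)]
    rows = []
    # TFs beyond the first may be regulated by earlier TFs
    for i, tf in enumerate(tfs):
        if i == 0:
            continue
        k = min(int(rng.poisson(spec.mean_in_degree / 2.0)), i)
        for parent in rng.choice(tfs[:i], size=k, replace=False):
            sign = 1 if rng.random() < spec.activation_fraction else -1
            rows.append((parent, tf, sign))
    # every non-TF target has at least one parent
    for target in targets:
        k = min(max(int(rng.poisson(spec.mean_in_degree)), 1), spec.n_tf)
        for parent in rng.choice(tfs, size=k, replace=False):
            sign = 1 if rng.random() < spec.activation_fraction else -1
            rows.append((parent, target, sign))
    edges = pd.DataFrame(rows, columns=["tf_id", "target_id", "sign"])
    return GroundTruthNetwork(
        edges=edges, tf_ids=tfs, target_ids=targets, order=tfs + targets
    )


def simulate_expression(
    net: GroundTruthNetwork,
    n_cells: int = 300,
    spec: SimulationSpec | None = None,
    counts: bool = True,
) -> ExpressionMatrix:
    """Steady-state kinetic expression profiles for every gene.

    Root genes draw lognormal baselines; each downstream gene's mean is
    ``(v / lambda) * prod(Hill terms over parents)`` (activators
    ``x^h / (K^h + x^h)``, repressors ``K^h / (K^h + x^h)``) evaluated
    in topological order, times multiplicative lognormal cell noise.
    With ``counts=True``, Poisson read counts are drawn at the
    configured library depth; otherwise the underlying rates are
    returned.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng([spec.seed, 1])
    genes = net.gene_ids
    parents = {g: [] for g in genes}
    signs: dict[tuple[str, str], int] = {}
    for row in net.edges.itertuples():
        parents[row.target_id].append(row.tf_id)
        signs[(row.tf_id, row.target_id)] = int(row.sign)

    x = pd.DataFrame(0.0, index=genes, columns=range(n_cells))
    scale = spec.production / spec.degradation
    kh = spec.k_half ** spec.hill
    for g in genes:  # topological order
        noise = (
            np.exp(rng.normal(0.0, spec.noise_sd, size=n_cells))
            if spec.noise_sd > 0 else np.ones(n_cells)
        )
        if not parents[g]:
            base = (
                np.exp(rng.normal(spec.root_log_mean, spec.root_log_sd,
                                  size=n_cells))
                if spec.root_log_sd > 0
                else np.full(n_cells, np.exp(spec.root_log_mean))
            )
            x.loc[g] = base * noise
            continue
        mean = np.full(n_cells, scale)
        for p in parents[g]:
            xp = x.loc[p].to_numpy() ** spec.hill
            hill = xp / (kh + xp)
            if signs[(p, g)] < 0:
                hill = kh / (kh + xp)
            mean = mean * hill
        x.loc[g] = mean * noise
    if not counts:
        return ExpressionMatrix(
            x.rename(columns=lambda c: f"cell{c + 1}"), normalized=False
        )
    rates = x.to_numpy()
    totals = rates.sum(axis=0, keepdims=True)
    lam = rates / totals * spec.library_depth
    draws = rng.poisson(lam)
    out = pd.DataFrame(
        draws.astype(float), index=genes,
        columns=[f"cell{c + 1}" for c in range(n_cells)],
    )
    return ExpressionMatrix(out, normalized=False)


def simulate_prior(
    net: GroundTruthNetwork,
    n_decoys: int,
    seed: int,
    targets: Iterable[str] | None = None,
) -> PriorNetwork:
    """Decoy-augmented prior: true parents plus random non-parent TFs."""
    if n_decoys < 0:
        raise ValidationError("n_decoys must be >= 0")
    rng = np.random.default_rng([seed, 2])
    targets = list(targets) if targets is not None else list(net.target_ids)
    parents: dict[str, frozenset[str]] = {}
    capped = False
    for target in targets:
        true = set(net.parents_of(target))
        pool = sorted(set(net.tf_ids) - true - {target})
        k = n_decoys
        if k > len(pool):
            capped = True
            k = len(pool)
        decoys = (
            set(rng.choice(pool, size=k, replace=False)) if k else set()
        )
        cand = true | decoys
        if cand:
            parents[target] = frozenset(cand)
    if capped:
        warnings.warn(
            "n_decoys exceeded the available non-parent TFs; capped",
            stacklevel=2,
        )
    return PriorNetwork(parents=parents, provenance="synthetic")


@dataclass
class EpigenomeSim:
    """Bundle returned by :func:`simulate_epigenome`."""

    rankings: MotifRankingMatrix
    signal: RegionSignalMatrix
    regions: RegionSet
    tss: TssTable
    truth: pd.DataFrame          # planted (motif_id, tf_id, region_id, gene_id)
    active_motifs: list[str]


def simulate_epigenome(
    n_regions: int,
    n_motifs: int,
    active_motifs: Iterable[str] | int,
    effect: float,
    mode: str = "methylation",
    n_samples: int = 6,
    seed: int = 0,
    top_frac: float = 0.05,
    frac_regions_with_gene: float = 0.7,
    base_rate: float = 0.5,
    signal_noise_sd: float = 0.1,
) -> EpigenomeSim:
    """Motif rankings plus epigenomic signal with planted associations.

    Regions sit on one synthetic chromosome, spaced so that each
    region's own gene (present for ``frac_regions_with_gene`` of
    regions) is the only promoter within 5 kb.  Per-motif match scores
    are standard normal; ranks are their descending order.  For active
    motifs, the signal tracks the mean standardized score of the active
    set: methylation rates fall (binding protects from methylation) and
    peak probability rises with better matches.  Inactive motifs are
    independent of the signal.  The planted truth lists, per active
    motif, its matched regions (best ``top_frac``) that map to a gene.
    """
    if mode not in ("methylation", "peaks"):
        raise ValidationError(f"unknown mode {mode!r}")
    if effect < 0:
        raise ValidationError("effect must be >= 0")
    rng = np.random.default_rng([seed, 3])
    motif_ids = [f"motif{i + 1}" for i in range(n_motifs)]
    if isinstance(active_motifs, int):
        if active_motifs > n_motifs:
            raise ValidationError("more active motifs than motifs")
        active = motif_ids[:active_motifs]
    else:
        active = [str(m) for m in active_motifs]
        unknown = set(active) - set(motif_ids)
        if unknown:
            raise ValidationError(f"active motifs not in motif set: {unknown}")

    spacing = 20_000  # own gene is the only promoter within 5 kb
    length = 200
    region_ids = [f"r{i + 1}" for i in range(n_regions)]
    regions = RegionSet(pd.DataFrame({
        "region_id": region_ids,
        "chrom": "chrS",
        "start": [i * spacing for i in range(n_regions)],
        "end": [i * spacing + length for i in range(n_regions)],
    }))
    has_gene = rng.random(n_regions) < frac_regions_with_gene
    tss_rows = [
        (f"g{i + 1}", "chrS", i * spacing + length + 300, "+")
        for i in range(n_regions) if has_gene[i]
    ]
    if not tss_rows:  # degenerate draw; force one gene
        tss_rows = [("g1", "chrS", length + 300, "+")]
    tss = TssTable(pd.DataFrame(
        tss_rows, columns=["gene_id", "chrom", "tss", "strand"]
    ))

    scores = rng.normal(size=(n_motifs, n_regions))
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_motifs)[:, None]
    ranks[rows, order] = np.arange(1, n_regions + 1)
    rankings = MotifRankingMatrix(
        pd.DataFrame(ranks, index=motif_ids, columns=region_ids),
        motif_to_tf={m: (m.replace("motif", "TF"),) for m in motif_ids},
    )

    active_idx = [motif_ids.index(m) for m in active]
    if active_idx:
        z = scores[active_idx].mean(axis=0)
        z = (z - z.mean()) / z.std()
    else:
        z = np.zeros(n_regions)

    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    values = np.empty((n_regions, n_samples))
    if mode == "methylation":
        for j in range(n_samples):
            eps = rng.normal(0.0, signal_noise_sd, size=n_regions)
            values[:, j] = np.clip(base_rate - effect * z + eps, 0.0, 1.0)
        kind = "methylation"
    else:
        base_logit = logit(np.clip(base_rate, 1e-6, 1 - 1e-6))
        for j in range(n_samples):
            for _attempt in range(20):
                eps = rng.normal(0.0, signal_noise_sd, size=n_regions)
                prob = expit(base_logit + effect * z + eps)
                col = (rng.random(n_regions) < prob).astype(float)
                if 0 < col.sum() < n_regions:
                    break
                warnings.warn(
                    "degenerate peak column; regenerating", stacklevel=2
                )
            values[:, j] = col
        kind = "binary"
    signal = RegionSignalMatrix(
        values=pd.DataFrame(values, index=region_ids, columns=sample_ids),
        kind=kind,
    )

    gene_of = assign_regions_to_genes(regions, tss, max_dist=5000).as_dict()
    truth_rows = []
    for m in active:
        tf = rankings.motif_to_tf[m][0]
        for r in matched_regions(rankings, m, top_frac):
            if r in gene_of:
                truth_rows.append((m, tf, r, gene_of[r][0]))
    truth = pd.DataFrame(
        truth_rows, columns=["motif_id", "tf_id", "region_id", "gene_id"]
    )
    return EpigenomeSim(
        rankings=rankings, signal=signal, regions=regions, tss=tss,
        truth=truth, active_motifs=list(active),
    )
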