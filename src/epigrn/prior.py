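"""Epigenomic prior network construction.

Two variants of the same idea: test, per TF motif and per sample,
whether the closeness of the motif's sequence match across candidate
cis-regulatory regions is associated with the epigenomic signal
observed at those regions.

* **MLC** (modified lever/cisTarget): binary signal (peak presence);
  association measured by Somers' D.
* **MethCorTarget**: region-average DNA-methylation rates in [0, 1];
  association measured by Spearman correlation.

Either statistic is converted to an approximate standard-normal z by
the Fisher transform scaled by ``sqrt(R - 3)``, and a motif is retained
per sample when the two-sided p-value falls below ``alpha`` (default
0.1).  Motifs retained under the sample-aggregation rule contribute
edges from their TF(s) to the genes whose promoters lie within
``max_dist`` of the motif's best-matched regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._exceptions import UndefinedStatisticError, ValidationError
from .io import (
    CpGCountTable,
    MotifRankingMatrix,
    RegionSet,
    RegionSignalMatrix,
    TssTable,
)
from .stats import fisher_z_test, somers_d, spearman_rho

__all__ = [
    "RegionGeneMap",
    "PriorNetwork",
    "PriorNetworkModel",
    "PriorNetworkResults",
    "aggregate_region_methylation",
    "matched_regions",
    "assign_regions_to_genes",
    "build_prior_mlc",
    "build_prior_methcor",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RegionGeneMap:
    """region_id -> (gene_id, distance in bp), one gene per region."""

    df: pd.DataFrame  # columns: region_id, gene_id, distance

    def __post_init__(self) -> None:
        required = ["region_id", "gene_id", "distance"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"RegionGeneMap missing columns {missing}")
        if self.df["region_id"].duplicated().any():
            raise ValidationError("a region maps to more than one gene")
        self.df = self.df.loc[:, required].reset_index(drop=True)

    def as_dict(self) -> dict[str, tuple[str, int]]:
        return {
            r.region_id: (r.gene_id, int(r.distance))
            for r in self.df.itertuples()
        }

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PriorNetwork:
    """Target-specific candidate-regulator sets with region support.

    ``parents`` maps each target gene to its candidate TF set
    ``PA_prior(target)``; ``support`` maps (tf, target) to the region
    ids that back the edge.  ``provenance`` records how the network was
    built ('mlc', 'methcor' or 'synthetic').
    """

    parents: dict[str, frozenset[str]]
    support: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        clean = {}
        for target, tfs in self.parents.items():
            tfs = frozenset(tfs)
            if not tfs:
                raise ValidationError(
                    f"target {target!r} listed with an empty candidate set"
                )
            clean[str(target)] = tfs
        self.parents = clean
        self.support = {
            (str(a), str(b)): frozenset(v)
            for (a, b), v in self.support.items()
        }

    @property
    def targets(self) -> list[str]:
        return sorted(self.parents)

    @property
    def tfs(self) -> list[str]:
        out: set[str] = set()
        for tfs in self.parents.values():
            out |= tfs
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.parents.values())

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (tf, target)
            for target, tfs in self.parents.items()
            for tf in tfs
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tf, target in self.edges():
            sup = ",".join(sorted(self.support.get((tf, target), ())))
            rows.append((tf, target, sup))
        return pd.DataFrame(rows, columns=["tf_id", "target_id", "support_regions"])

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PriorNetwork":
        provenance = "synthetic"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# provenance:"):
                provenance = first.split(":", 1)[1].strip()
                df = pd.read_csv(fh, sep="\t", dtype=str)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype=str)
        parents: dict[str, set[str]] = {}
        support: dict[tuple[str, str], set[str]] = {}
        for row in df.itertuples():
            parents.setdefault(row.target_id, set()).add(row.tf_id)
            sup = getattr(row, "support_regions", "")
            if isinstance(sup, str) and sup:
                support[(row.tf_id, row.target_id)] = set(sup.split(","))
        return cls(
            parents={t: frozenset(v) for t, v in parents.items()},
            support={k: frozenset(v) for k, v in support.items()},
            provenance=provenance,
        )


# ---------------------------------------------------------------------------
# region-level operations
# ---------------------------------------------------------------------------

def aggregate_region_methylation(
    cpgs: CpGCountTable,
    regions: RegionSet,
    min_reads: int = 10,
) -> RegionSignalMatrix:
    """Aggregate CpG counts into region-average methylation rates.

    For each region and sample, the rate is total methylated reads over
    total reads across all CpGs inside the region; entries with fewer
    than ``min_reads`` total reads are flagged uncovered.
    """
    if len(regions) == 0:
        raise ValidationError("empty region set")
    samples = cpgs.sample_ids
    region_ids = regions.region_ids
    meth = pd.DataFrame(0.0, index=region_ids, columns=samples)
    total = pd.DataFrame(0.0, index=region_ids, columns=samples)

    cdf = cpgs.df
    any_hit = False
    for chrom, rsub in regions.df.groupby("chrom"):
        csub = cdf[cdf["chrom"] == chrom]
        if csub.empty:
            continue
        pos = csub["position"].to_numpy()
        for reg in rsub.itertuples():
            mask = (pos >= reg.start) & (pos < reg.end)
            if not mask.any():
                continue
            any_hit = True
            hit = csub.loc[mask]
            agg = hit.groupby("sample_id")[
                ["count_methylated", "count_unmethylated"]
            ].sum()
            m = agg["count_methylated"]
            t = agg["count_methylated"] + agg["count_unmethylated"]
            meth.loc[reg.region_id, m.index] = m.to_numpy(dtype=float)
            total.loc[reg.region_id, t.index] = t.to_numpy(dtype=float)
    if not any_hit:
        warnings.warn(
            "no CpG falls inside any region; all entries uncovered",
            stacklevel=2,
        )
    coverage = total >= float(min_reads)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = meth.to_numpy() / total.to_numpy()
    rates = np.where(coverage.to_numpy(), rates, 0.0)
    values = pd.DataFrame(rates, index=region_ids, columns=samples)
    return RegionSignalMatrix(values=values, coverage=coverage, kind="methylation")


def matched_regions(
    rankings: MotifRankingMatrix,
    motif: str,
    top_frac: float = 0.05,
) -> list[str]:
    """Region ids a motif is 'matched' to: rank <= ceil(top_frac * R)."""
    if not (0 < top_frac <= 1):
        raise ValidationError("top_frac must lie in (0, 1]")
    if motif not in rankings.ranks.index:
        raise ValidationError(f"unknown motif id {motif!r}")
    R = rankings.n_regions
    cutoff = math.ceil(top_frac * R)
    row = rankings.ranks.loc[motif]
    return row.index[row.to_numpy() <= cutoff].tolist()


def assign_regions_to_genes(
    regions: RegionSet,
    tss: TssTable,
    max_dist: int = 5000,
) -> RegionGeneMap:
    """Assign each region to the gene with the closest promoter (< max_dist).

    Distance is 0 when the TSS falls inside the region, otherwise the
    gap to the nearest end.  Regions whose closest TSS is at or beyond
    ``max_dist`` are dropped.  Exact-distance ties break by
    lexicographic gene id.
    """
    if len(tss) == 0:
        raise ValidationError("empty TSS table")
    rows = []
    tss_sorted = tss.df.sort_values(["chrom", "tss", "gene_id"])
    for chrom, rsub in regions.df.groupby("chrom"):
        tsub = tss_sorted[tss_sorted["chrom"] == chrom]
        if tsub.empty:
            continue
        positions = tsub["tss"].to_numpy()
        genes = tsub["gene_id"].to_numpy()
        for reg in rsub.itertuples():
            # gap to the interval: 0 for a TSS inside [start, end)
            d = np.maximum.reduce([
                reg.start - positions, positions - reg.end,
                np.zeros_like(positions),
            ])
            best = d.min()
            if best >= max_dist:
                continue
            cand = genes[d == best]
            rows.append((reg.region_id, sorted(cand)[0], int(best)))
    df = pd.DataFrame(rows, columns=["region_id", "gene_id", "distance"])
    return RegionGeneMap(df)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PriorNetworkResults:
    """Fitted epigenomic prior network and its association statistics.

    Attributes
    ----------
    network : PriorNetwork
        Candidate-regulator sets with supporting regions.
    associations : pandas.DataFrame
        One row per (motif, sample): statistic, z, p, R_used, retained.
    retained_motifs : list of str
        Motifs retained under the sample-aggregation rule.
    region_gene_map : RegionGeneMap
        Promoter assignment used for edge construction.
    """

    def __init__(self, model, network, associations, retained_motifs,
                 region_gene_map):
        self.model = model
        self.network = network
        self.associations = associations
        self.retained_motifs = retained_motifs
        self.region_gene_map = region_gene_map

    def summary(self) -> str:
        m = self.model
        n_motifs = len(m.rankings.motif_ids)
        lines = [
            "Epigenomic prior network",
            "=" * 40,
            f"method:            {m.method}",
            f"motifs tested:     {n_motifs}",
            f"motifs retained:   {len(self.retained_motifs)}",
            f"regions:           {m.rankings.n_regions}",
            f"samples:           {len(m.signal.sample_ids)}",
            f"alpha:             {m.alpha}",
            f"top_frac:          {m.top_frac}",
            f"max_dist:          {m.max_dist}",
            f"targets:           {len(self.network.parents)}",
            f"edges:             {self.network.n_edges}",
        ]
        return "\n".join(lines)


class PriorNetworkModel:
    """Build an epigenomic prior network from motif rankings and signal.

    Parameters
    ----------
    rankings : MotifRankingMatrix
        Per-motif rank of each region's sequence match (1 = best).
    signal : RegionSignalMatrix
        Binary peak presence (``method='mlc'``) or methylation rates
        (``method='methcor'``) per region and sample.
    regions : RegionSet
        Coordinates of the candidate regions.
    tss : TssTable
        Promoter annotation for region-to-gene assignment.
    method : {'mlc', 'methcor'}
    alpha : float
        Per-sample retention threshold on the Fisher-z p-value.
    top_frac : float
        A motif is 'matched' to a region when its rank is within the
        best ``top_frac`` fraction of regions.
    max_dist : int
        Maximum promoter distance (bp, exclusive) for edge assignment.
    sample_rule : {'majority'} or int
        Motif retained overall when significant in a strict majority of
        assessable samples, or in at least this many samples.
    min_covered_samples : {'majority'} or int
        (methcor) A region enters the correlations only when covered in
        at least this many samples.
    """

    def __init__(
        self,
        rankings: MotifRankingMatrix,
        signal: RegionSignalMatrix,
        regions: RegionSet,
        tss: TssTable,
        method: str = "methcor",
        alpha: float = 0.1,
        top_frac: float = 0.05,
        max_dist: int = 5000,
        sample_rule: str | int = "majority",
        min_covered_samples: str | int = 3,
    ):
        if method not in ("mlc", "methcor"):
            raise ValidationError(f"unknown method {method!r}")
        if method == "mlc" and signal.kind != "binary":
            raise ValidationError("MLC requires a binary signal")
        if method == "methcor" and signal.kind != "methylation":
            raise ValidationError("MethCorTarget requires methylation rates")
        self.rankings = rankings
        self.signal = signal
        self.regions = regions
        self.tss = tss
        self.method = method
        self.alpha = alpha
        self.top_frac = top_frac
        self.max_dist = max_dist
        self.sample_rule = sample_rule
        self.min_covered_samples = min_covered_samples

    # -- helpers ----------------------------------------------------------

    def _required_count(self, rule: str | int, n: int) -> int:
        if rule == "majority":
            return n // 2 + 1  # strict majority
        k = int(rule)
        if k < 1:
            raise ValidationError("sample threshold must be >= 1")
        return k

    def _usable_regions(self) -> list[str]:
        """Regions present in rankings, signal and the region set, and
        (methcor) covered in enough samples."""
        common = [
            r for r in self.regions.region_ids
            if r in self.signal.values.index and r in self.rankings.ranks.columns
        ]
        if self.method == "mlc":
            return common
        need = self._required_count(
            self.min_covered_samples, len(self.signal.sample_ids)
        )
        cov = self.signal.coverage.loc[common]
        keep = cov.sum(axis=1) >= need
        return [r for r, k in zip(common, keep) if k]

    # -- fitting ----------------------------------------------------------

    def fit(self) -> PriorNetworkResults:
        signal = self.signal
        usable = self._usable_regions()
        samples = signal.sample_ids
        n_samples = len(samples)
        need_sig = self._required_count(self.sample_rule, n_samples)

        assoc_rows = []
        retained: list[str] = []
        for motif in self.rankings.motif_ids:
            # match closeness: negated rank, so larger = better match
            closeness_all = -self.rankings.ranks.loc[motif]
            n_sig = 0
            n_defined = 0
            motif_rows = []
            for sample in samples:
                cov = signal.coverage.loc[usable, sample].to_numpy(dtype=bool)
                ids = [r for r, c in zip(usable, cov) if c]
                r_used = len(ids)
                row = {
                    "motif_id": motif, "sample_id": sample,
                    "statistic": np.nan, "z": np.nan, "p": np.nan,
                    "R_used": r_used, "retained_sample": False,
                }
                if r_used >= 4:
                    x = closeness_all.loc[ids].to_numpy(dtype=float)
                    y = signal.values.loc[ids, sample].to_numpy(dtype=float)
                    try:
                        if self.method == "mlc":
                            stat = somers_d(x, y.astype(int)).d
                        else:
                            stat = spearman_rho(x, y)
                        fz = fisher_z_test(stat, r_used)
                        row.update(statistic=stat, z=fz.z, p=fz.p)
                        n_defined += 1
                        if fz.p < self.alpha:
                            row["retained_sample"] = True
                            n_sig += 1
                    except UndefinedStatisticError:
                        pass  # skipped for this sample
                motif_rows.append(row)
            assoc_rows.extend(motif_rows)
            if n_defined > 0 and n_sig >= 1:
                if self.sample_rule == "majority":
                    # strict majority of samples with a defined statistic
                    if n_sig > n_defined / 2:
                        retained.append(motif)
                elif n_sig >= need_sig:
                    retained.append(motif)

        associations = pd.DataFrame(assoc_rows)
        rg_map = assign_regions_to_genes(self.regions, self.tss, self.max_dist)
        gene_of = rg_map.as_dict()

        parents: dict[str, set[str]] = {}
        support: dict[tuple[str, str], set[str]] = {}
        usable_set = set(usable)
        for motif in retained:
            hit_regions = [
                r for r in matched_regions(self.rankings, motif, self.top_frac)
                if r in usable_set and r in gene_of
            ]
            for tf in self.rankings.motif_to_tf[motif]:
                for r in hit_regions:
                    gene = gene_of[r][0]
                    parents.setdefault(gene, set()).add(tf)
                    support.setdefault((tf, gene), set()).add(r)
        if not parents:
            warnings.warn("no motif retained; prior network is empty",
                          stacklevel=2)
        network = PriorNetwork(
            parents={t: frozenset(v) for t, v in parents.items()},
            support={k: frozenset(v) for k, v in support.items()},
            provenance=self.method,
        )
        return PriorNetworkResults(
            self, network, associations, retained, rg_map
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def build_prior_mlc(
    signal: RegionSignalMatrix,
    rankings: MotifRankingMatrix,
    regions: RegionSet,
    tss: TssTable,
    alpha: float = 0.1,
    top_frac: float = 0.05,
    max_dist: int = 5000,
    sample_rule: str | int = "majority",
) -> PriorNetworkResults:
    """Prior network from binary chromatin signal via Somers' D (MLC)."""
    return PriorNetworkModel(
        rankings, signal, regions, tss, method="mlc", alpha=alpha,
        top_frac=top_frac, max_dist=max_dist, sample_rule=sample_rule,
    ).fit()


def build_prior_methcor(
    signal: RegionSignalMatrix,
    rankings: MotifRankingMatrix,
    regions: RegionSet,
    tss: TssTable,
    alpha: float = 0.1,
    top_frac: float = 0.05,
    max_dist: int = 5000,
    sample_rule: str | int = "majority",
    min_covered_samples: str | int = 3,
) -> PriorNetworkResults:
    """Prior network from DNAme rates via Spearman correlation
    (MethCorTarget)."""
    return PriorNetworkModel(
        rankings, signal, regions, tss, method="methcor", alpha=alpha,
        top_frac=top_frac, max_dist=max_dist, sample_rule=sample_rule,
        min_covered_samples=min_covered_samples,
    ).fit()
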