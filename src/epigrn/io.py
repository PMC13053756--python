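"""Readers and writers for the tabular formats the package consumes.

All genomic coordinates are held internally as 0-based, half-open
intervals (the BED convention).  Bismark coverage files, which are
1-based, are shifted on read.  Readers validate type invariants and
raise :class:`~epigrn._exceptions.ValidationError` rather than silently
coercing bad input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import ParseError, ValidationError

__all__ = [
    "RegionSet",
    "CpGCountTable",
    "TssTable",
    "ExpressionMatrix",
    "EdgeList",
    "MotifRankingMatrix",
    "RegionSignalMatrix",
    "read_region_table",
    "read_methylation_counts",
    "read_motif_rankings",
    "read_tss_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "write_region_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """A set of genomic intervals (0-based, half-open).

    ``df`` has columns ``region_id, chrom, start, end`` with unique
    region ids.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["region_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"RegionSet missing columns {missing}")
        df = self.df.loc[:, required].reset_index(drop=True)
        if df[["start", "end"]].isna().any().any():
            raise ValidationError("RegionSet has NaN coordinates")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"region {df['region_id'].iat[i]!r}: start >= end "
                f"({df['start'].iat[i]} >= {df['end'].iat[i]})"
            )
        if df["region_id"].duplicated().any():
            dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
            raise ValidationError(f"duplicate region_id {dup!r}")
        self.df = df

    @property
    def region_ids(self) -> list[str]:
        return self.df["region_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CpGCountTable:
    """Per-CpG methylated/unmethylated read counts for one or more samples.

    Positions are 0-based single bases.  (chrom, position, sample_id)
    is unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "position", "count_methylated",
                    "count_unmethylated", "sample_id"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"CpGCountTable missing columns {missing}")
        df = self.df.loc[:, required].reset_index(drop=True)
        for c in ("count_methylated", "count_unmethylated"):
            if (df[c] < 0).any():
                raise ValidationError(f"negative values in {c}")
        if df.duplicated(["chrom", "position", "sample_id"]).any():
            raise ValidationError("duplicate (chrom, position, sample_id)")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique().tolist())


@dataclass
class TssTable:
    """Transcription start sites: gene_id, chrom, tss (0-based), strand."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"TssTable missing columns {missing}")
        df = self.df.loc[:, required].reset_index(drop=True)
        if df.duplicated(["gene_id", "tss"]).any():
            raise ValidationError("duplicate (gene_id, tss) records")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError("strand must be '+' or '-'")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``normalized`` records whether CPM scaling has been applied, so the
    normaliser can refuse to run twice.
    """

    values: pd.DataFrame          # genes x samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeList:
    """Weighted TF -> target edges with a selection flag."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["tf_id", "target_id", "weight", "selected"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"EdgeList missing columns {missing}")
        df = self.df.loc[:, list(self.df.columns)].reset_index(drop=True)
        if df.duplicated(["tf_id", "target_id"]).any():
            raise ValidationError("duplicate (tf_id, target_id) pair")
        if (df["weight"] < 0).any():
            raise ValidationError("edge weights must be >= 0")
        df["selected"] = df["selected"].astype(bool)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MotifRankingMatrix:
    """Per-motif rank of every candidate region's sequence match.

    ``ranks`` is motifs x regions; each row is a permutation of
    ``1..R`` with rank 1 the best match.  ``motif_to_tf`` maps each
    motif id to one or more TF gene ids (identity map by default).
    """

    ranks: pd.DataFrame
    motif_to_tf: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = self.ranks
        R = ranks.shape[1]
        arr = ranks.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("ranks must be integers")
            arr = arr.astype(np.int64)
            ranks = pd.DataFrame(arr, index=ranks.index, columns=ranks.columns)
        expected = np.arange(1, R + 1)
        for motif, row in zip(ranks.index, arr):
            if not np.array_equal(np.sort(row), expected):
                raise ValidationError(
                    f"motif {motif!r}: row is not a permutation of 1..{R}"
                )
        if not self.motif_to_tf:
            self.motif_to_tf = {m: (str(m),) for m in ranks.index}
        else:
            self.motif_to_tf = {
                m: tuple(v) if not isinstance(v, str) else (v,)
                for m, v in self.motif_to_tf.items()
            }
            missing = [m for m in ranks.index if m not in self.motif_to_tf]
            if missing:
                raise ValidationError(
                    f"motifs without a TF mapping: {missing[:5]}"
                )
        self.ranks = ranks

    @property
    def motif_ids(self) -> list[str]:
        return self.ranks.index.tolist()

    @property
    def region_ids(self) -> list[str]:
        return self.ranks.columns.tolist()

    @property
    def n_regions(self) -> int:
        return self.ranks.shape[1]

    def align_regions(self, region_ids: Iterable[str]) -> "MotifRankingMatrix":
        """Reorder the region columns to match ``region_ids`` (id join)."""
        ids = list(region_ids)
        missing = [r for r in ids if r not in self.ranks.columns]
        if missing:
            raise ValidationError(f"regions absent from rankings: {missing[:5]}")
        return MotifRankingMatrix(self.ranks.loc[:, ids], dict(self.motif_to_tf))


@dataclass
class RegionSignalMatrix:
    """Per-region, per-sample epigenomic signal.

    ``values`` is regions x samples; entries are DNA-methylation rates
    in [0, 1] (``kind='methylation'``) or peak presence in {0, 1}
    (``kind='binary'``).  ``coverage`` marks entries backed by data;
    values where coverage is False are ignored downstream.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame | None = None
    kind: str = "methylation"

    def __post_init__(self) -> None:
        if self.kind not in ("methylation", "binary"):
            raise ValidationError(f"unknown signal kind {self.kind!r}")
        if self.coverage is None:
            self.coverage = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if self.coverage.shape != self.values.shape:
            raise ValidationError("coverage shape mismatch")
        vals = self.values.to_numpy(dtype=float)
        cov = self.coverage.to_numpy(dtype=bool)
        v = vals[cov]
        if self.kind == "methylation":
            if ((v < 0) | (v > 1)).any():
                raise ValidationError("methylation rates must be in [0, 1]")
        else:
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValidationError("binary signal must be 0/1")

    @property
    def region_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_region_table(path: str | Path) -> RegionSet:
    """Read a BED (3+ column) file into a :class:`RegionSet`.

    Coordinates are kept 0-based half-open.  The 4th column supplies
    region ids where present; otherwise ids are synthesised as
    ``chrom:start-end``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") \
                else f"{chrom}:{start}-{end}"
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])
    return RegionSet(df)


def write_region_table(regions: RegionSet, path: str | Path) -> None:
    """Write a :class:`RegionSet` as 4-column BED."""
    out = regions.df[["chrom", "start", "end", "region_id"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_methylation_counts(path: str | Path, sample_id: str) -> CpGCountTable:
    """Read a Bismark coverage file for one sample.

    Format: chrom, start, end (1-based), methylation %, count
    methylated, count unmethylated.  Positions are shifted to 0-based;
    the percent column is ignored (recomputable from the counts) but a
    gross inconsistency with the counts triggers a warning.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "percent", "count_methylated",
               "count_unmethylated"],
        dtype={"chrom": str},
    )
    if ((df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)).any():
        raise ValidationError(f"{path}: negative read counts")
    tot = df["count_methylated"] + df["count_unmethylated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = 100.0 * df["count_methylated"] / tot
    mism = tot > 0
    mism &= (implied - df["percent"]).abs() > 1.0
    if mism.any():
        warnings.warn(
            f"{path}: {int(mism.sum())} rows where the percent column "
            "disagrees with the counts; counts take precedence",
            stacklevel=2,
        )
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "position": df["start"].astype(np.int64) - 1,  # 1-based -> 0-based
        "count_methylated": df["count_methylated"].astype(np.int64),
        "count_unmethylated": df["count_unmethylated"].astype(np.int64),
        "sample_id": sample_id,
    })
    return CpGCountTable(out)


def read_motif_rankings(path: str | Path) -> MotifRankingMatrix:
    """Read a motif-by-region rank matrix from TSV.

    First column holds motif ids; remaining columns are region ids with
    integer rank entries.  Each row must be a permutation of ``1..R``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MotifRankingMatrix(df)


def write_motif_rankings(rankings: MotifRankingMatrix, path: str | Path) -> None:
    out = rankings.ranks.copy()
    out.index.name = "motif_id"
    out.to_csv(path, sep="\t")


def read_tss_table(path: str | Path) -> TssTable:
    """Read a TSS annotation TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return TssTable(df)


def write_tss_table(tss: TssTable, path: str | Path) -> None:
    tss.df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path, normalized: bool = False) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, normalized=normalized)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a TSV edge list with columns tf_id, target_id, weight, selected."""
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "target_id": str})
    if df.duplicated(["tf_id", "target_id"]).any():
        raise ValidationError(f"{path}: duplicate (tf, target) pair")
    return EdgeList(df)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    """Write an edge list as TSV; round-trips ids, weights and flags."""
    df = edges.df.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
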