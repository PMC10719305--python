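"""Data model and I/O for clinical survival tables and gene-level methylation.

The analysis dataset couples three ingredients: a clinical table with overall
survival time (days) and a vital-status indicator, a gene x sample matrix of
average promoter methylation (beta values in (0, 1]), and, optionally, a
promoter BED map used to aggregate per-CpG calls into gene-level averages.
Covariates enter the downstream models as natural-log-transformed average
methylation; the response is the natural log of survival time in days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "GeneMethylationMatrix",
    "PromoterMap",
    "SurvivalDataset",
    "read_survival_table",
    "read_methylation_matrix",
    "read_promoter_bed",
    "aggregate_promoter_methylation",
    "build_dataset",
    "write_dataset",
    "read_dataset",
]


class ConfigurationError(ValueError):
    """A required column or setting is missing or malformed."""


class DataError(ValueError):
    """The input data cannot support the requested analysis."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: observed time in days and event indicator.

    ``status`` is 1 for an observed event (deceased) and 0 for
    right-censoring.
    """

    sample_id: str
    time: float
    status: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status}")


@dataclass
class GeneMethylationMatrix:
    """Average promoter methylation (beta scale) per gene and sample."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), entries in (0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise DataError("methylation matrix contains missing entries")


@dataclass
class PromoterMap:
    """Promoter intervals per gene, BED convention (0-based, half-open)."""

    intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def add(self, gene: str, chrom: str, start: int, end: int) -> None:
        if not start < end:
            raise ValueError(f"{gene}: interval start {start} >= end {end}")
        self.intervals.setdefault(gene, []).append((chrom, int(start), int(end)))

    @property
    def genes(self) -> list[str]:
        return list(self.intervals)


@dataclass
class SurvivalDataset:
    """Aligned analysis dataset.

    ``X`` holds log-transformed covariates (n x p), ``y`` the natural log of
    observed survival times, and ``delta`` the event indicators.
    """

    X: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    gene_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        n, p = self.X.shape
        if len(self.y) != n or len(self.delta) != n or len(self.sample_ids) != n:
            raise ValueError("row counts of X, y, delta, sample_ids disagree")
        if len(self.gene_names) != p:
            raise ValueError("gene_names length does not match X columns")
        if not np.isfinite(self.y).all():
            raise DataError("y contains non-finite log survival times")
        if not np.isin(self.delta, (0, 1)).all():
            raise DataError("delta must be 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_genes(self, genes: list[str]) -> "SurvivalDataset":
        idx = [self.gene_names.index(g) for g in genes]
        return SurvivalDataset(
            X=self.X[:, idx],
            y=self.y.copy(),
            delta=self.delta.copy(),
            gene_names=list(genes),
            sample_ids=list(self.sample_ids),
        )


_DEFAULT_COLUMNS = {"sample_id": "sample_id", "time": "time_days", "status": "status"}


def read_survival_table(
    path,
    column_map: dict | None = None,
    status_map: dict | None = None,
) -> list[SurvivalRecord]:
    """Read a clinical survival table (TSV/CSV, optionally gzipped).

    Parameters
    ----------
    column_map
        Maps logical names ``sample_id``, ``time``, ``status`` to the header
        names actually present in the file.
    status_map
        Optional mapping of raw status labels (e.g. ``{"Dead": 1, "Alive": 0}``)
        to 0/1 indicators.

    Rows with missing or non-positive time are dropped with a logged count.
    Duplicate sample ids are a hard error: the survival of a duplicated id is
    ambiguous.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(f"survival table is missing columns: {missing}")
    sid = df[cols["sample_id"]].astype(str)
    if sid.duplicated().any():
        dups = sorted(sid[sid.duplicated()].unique())
        raise DataError(f"duplicate sample ids in survival table: {dups}")
    time = pd.to_numeric(df[cols["time"]], errors="coerce")
    status_raw = df[cols["status"]]
    if status_map:
        status = status_raw.map(status_map)
    else:
        status = pd.to_numeric(status_raw, errors="coerce")
    bad = time.isna() | (time <= 0) | status.isna()
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing/non-positive time or status", n_dropped)
    keep = ~bad
    records = [
        SurvivalRecord(sample_id=s, time=float(t), status=int(d))
        for s, t, d in zip(sid[keep], time[keep], status[keep])
    ]
    if not records:
        raise DataError("no usable rows in survival table")
    return records


def read_methylation_matrix(path) -> GeneMethylationMatrix:
    """Read a gene x sample methylation matrix (first column = gene symbol)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GeneMethylationMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_promoter_bed(path) -> PromoterMap:
    """Read promoters from BED (chrom, start, end, name=gene), tab-separated."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=range(4),
    )
    pm = PromoterMap()
    for row in df.itertuples(index=False):
        pm.add(str(row.gene), str(row.chrom), int(row.start), int(row.end))
    return pm


def aggregate_promoter_methylation(
    cpg_table: pd.DataFrame,
    promoters: PromoterMap,
) -> GeneMethylationMatrix:
    """Average per-CpG beta values over each gene's promoter intervals.

    ``cpg_table`` has columns ``chrom``, ``pos`` (1-based CpG position) and one
    column per sample. A CpG at 1-based position q belongs to a BED interval
    [start, end) iff start <= q - 1 < end. Genes whose intervals capture no
    CpGs (including intervals on chromosomes absent from the CpG table) are
    dropped with a logged count.
    """
    required = {"chrom", "pos"}
    if not required.issubset(cpg_table.columns):
        raise ConfigurationError("cpg_table requires 'chrom' and 'pos' columns")
    sample_cols = [c for c in cpg_table.columns if c not in required]
    if not sample_cols:
        raise ConfigurationError("cpg_table has no sample columns")
    # sort CpGs per chromosome so intervals become searchsorted slices
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in cpg_table.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos0, kind="stable")
        by_chrom[str(chrom)] = (pos0[order], grp[sample_cols].to_numpy(dtype=float)[order])

    genes, rows = [], []
    n_dropped = 0
    missing_chroms: set[str] = set()
    for gene, intervals in promoters.intervals.items():
        chunks = []
        for chrom, start, end in intervals:
            if chrom not in by_chrom:
                missing_chroms.add(chrom)
                continue
            pos0, betas = by_chrom[chrom]
            lo, hi = np.searchsorted(pos0, [start, end])
            if hi > lo:
                chunks.append(betas[lo:hi])
        if not chunks:
            n_dropped += 1
            continue
        genes.append(gene)
        rows.append(np.concatenate(chunks, axis=0).mean(axis=0))
    if missing_chroms:
        logger.warning("intervals on chromosomes absent from CpG table: %s",
                       sorted(missing_chroms))
    if n_dropped:
        logger.warning("dropped %d genes with no mapped CpGs", n_dropped)
    if not genes:
        raise DataError("no gene promoter captured any CpG")
    return GeneMethylationMatrix(genes=genes, samples=list(sample_cols),
                                 values=np.vstack(rows))


def build_dataset(
    records: list[SurvivalRecord],
    matrix: GeneMethylationMatrix,
    pseudocount: float = 1e-6,
) -> SurvivalDataset:
    """Align clinical records with the methylation matrix and log-transform.

    Samples are restricted to the intersection of the two sources, in
    survival-table order. Beta values of exactly zero are replaced by
    ``pseudocount`` before taking the natural log so every covariate is finite.
    """
    col_of = {s: j for j, s in enumerate(matrix.samples)}
    kept = [r for r in records if r.sample_id in col_of]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.warning("dropped %d clinical samples absent from methylation matrix",
                       n_dropped)
    if not kept:
        raise DataError("no samples shared between survival table and matrix")
    cols = [col_of[r.sample_id] for r in kept]
    betas = matrix.values[:, cols].T  # n x p
    if (betas < 0).any() or (betas > 1).any():
        raise DataError("beta values outside [0, 1]")
    X = np.log(np.maximum(betas, pseudocount))
    return SurvivalDataset(
        X=X,
        y=np.log([r.time for r in kept]),
        delta=np.array([r.status for r in kept]),
        gene_names=list(matrix.genes),
        sample_ids=[r.sample_id for r in kept],
    )


def write_dataset(dataset: SurvivalDataset, path) -> None:
    """Write the aligned dataset as one TSV (sample_id, y, delta, genes...).

    Floats are written with 17 significant digits so a read-back is exact.
    """
    df = pd.DataFrame(dataset.X, columns=dataset.gene_names)
    df.insert(0, "delta", dataset.delta)
    df.insert(0, "y", dataset.y)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_dataset(path) -> SurvivalDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    genes = [c for c in df.columns if c not in ("sample_id", "y", "delta")]
    return SurvivalDataset(
        X=df[genes].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        delta=df["delta"].to_numpy(dtype=int),
        gene_names=genes,
        sample_ids=[str(s) for s in df["sample_id"]],
    )
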