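"""SNP quality filtering: from per-replicate count tables to one combined table.

The cascade runs, in order: per replicate, drop panel-flagged positions and
positions with implausibly high coverage (above the chosen percentile of a
Poisson with lambda = median coverage); then combine replicates by summing
counts per position; then discard positions missing either allele and trim
the coverage tails.  Every stage is a pure row-subset operation and logs
its input/output row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .pool_sim import SnpPanel

logger = logging.getLogger("bulkscan.snp_filter")

_COLUMNS = ["chrom", "pos", "count_a", "count_b"]


@dataclass
class SnpTable:
    """Per-SNP biallelic read counts for one replicate or combined pool.

    ``df`` columns: ``chrom`` (str), ``pos`` (1-based int), ``count_a``,
    ``count_b`` (non-negative ints).  Positions are unique within the
    table and sorted within each chromosome.
    """

    df: pd.DataFrame
    pool: str | None = None
    replicate: str | None = None

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        df = self.df.loc[:, _COLUMNS].reset_index(drop=True)
        if (df["count_a"] < 0).any() or (df["count_b"] < 0).any():
            raise ValueError("negative read counts")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ConsistencyError("duplicate (chrom, pos) rows in count table")
        for chrom, grp in df.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
                break
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coverage(self) -> np.ndarray:
        return (self.df["count_a"] + self.df["count_b"]).to_numpy()

    def subset(self, mask) -> "SnpTable":
        return SnpTable(self.df.loc[mask].reset_index(drop=True), self.pool, self.replicate)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the filter cascade."""

    poisson_percentile: float = 0.99
    tail_quantile: float = 0.01
    flags_to_drop: frozenset[str] = frozenset({"ambiguous_reference", "mismatch"})

    def __post_init__(self):
        if not (0.0 < self.poisson_percentile < 1.0):
            raise ValueError("poisson_percentile must be in (0, 1)")
        if not (0.0 <= self.tail_quantile < 0.5):
            raise ValueError("tail_quantile must be in [0, 0.5)")


def build_informative_panel(snp_list_a: pd.DataFrame, snp_list_b: pd.DataFrame) -> "SnpPanel":
    """Derive the discriminating SNP panel from two accession SNP lists.

    Each list has columns ``chrom, pos, ref, alt`` (reference base and the
    accession's base).  A position is kept when the two accession alleles
    differ, taking the reference base where an accession has no record;
    positions where both accessions carry the same variant are removed.
    """
    from .pool_sim import SnpPanel

    a = snp_list_a.rename(columns={"ref": "ref_a", "alt": "alt_a"})
    b = snp_list_b.rename(columns={"ref": "ref_b", "alt": "alt_b"})
    merged = a.merge(b, on=["chrom", "pos"], how="outer", sort=False)
    allele_a = merged["alt_a"].where(merged["alt_a"].notna(), merged["ref_b"])
    allele_b = merged["alt_b"].where(merged["alt_b"].notna(), merged["ref_a"])
    keep = allele_a != allele_b
    out = pd.DataFrame(
        {
            "chrom": merged.loc[keep, "chrom"],
            "pos": merged.loc[keep, "pos"].astype(np.int64),
            "allele_a": allele_a[keep],
            "allele_b": allele_b[keep],
        }
    )
    out["flags"] = [frozenset()] * len(out)
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    logger.info("informative panel: %d of %d merged positions kept", len(out), len(merged))
    return SnpPanel(out)


def drop_flagged(table: SnpTable, panel: "SnpPanel", config: FilterConfig) -> SnpTable:
    """Remove rows whose panel flags intersect ``config.flags_to_drop``."""
    key = pd.MultiIndex.from_frame(table.df[["chrom", "pos"]])
    panel_key = pd.MultiIndex.from_frame(panel.df[["chrom", "pos"]])
    idx = panel_key.get_indexer(key)
    if (idx < 0).any():
        n_bad = int((idx < 0).sum())
        raise ConsistencyError(f"{n_bad} table positions absent from the panel")
    flags = panel.df["flags"].to_numpy()[idx]
    bad = np.array([bool(f & config.flags_to_drop) for f in flags])
    out = table.subset(~bad)
    logger.info("drop_flagged: %d -> %d rows", len(table), len(out))
    return out


def poisson_coverage_cutoff(lam: float, percentile: float) -> int:
    """Smallest integer k with Poisson(lam) CDF >= percentile."""
    return int(stats.poisson.ppf(percentile, lam))


def filter_high_coverage(table: SnpTable, config: FilterConfig) -> SnpTable:
    """Drop rows with coverage above the Poisson percentile cutoff.

    lambda is the median per-SNP coverage of the table; rows strictly above
    the smallest integer k with ``Poisson(lambda) CDF >= percentile`` go.
    """
    if len(table) == 0:
        raise ValueError("cannot filter an empty table")
    cov = table.coverage
    lam = float(np.median(cov))
    cutoff = poisson_coverage_cutoff(lam, config.poisson_percentile)
    out = table.subset(cov <= cutoff)
    logger.info(
        "filter_high_coverage: lambda=%.1f cutoff=%d, %d -> %d rows",
        lam, cutoff, len(table), len(out),
    )
    return out


def combine_replicates(tables: Sequence[SnpTable]) -> SnpTable:
    """Sum read counts per SNP position across replicates.

    Positions present in only some replicates are zero-filled; the
    replicate id is cleared on the result.
    """
    if not tables:
        raise ValueError("no replicate tables to combine")
    pools = {t.pool for t in tables}
    if len(pools) > 1:
        raise ConsistencyError(f"replicates from different pools: {sorted(map(str, pools))}")
    merged = (
        pd.concat([t.df for t in tables], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=False)[["count_a", "count_b"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    out = SnpTable(merged, pool=tables[0].pool, replicate=None)
    logger.info("combine_replicates: %d tables -> %d rows", len(tables), len(out))
    return out


def drop_monoallelic(table: SnpTable) -> SnpTable:
    """Discard positions with zero reads for either allele."""
    mask = (table.df["count_a"] > 0) & (table.df["count_b"] > 0)
    out = table.subset(mask.to_numpy())
    logger.info("drop_monoallelic: %d -> %d rows", len(table), len(out))
    return out


def trim_coverage_quantiles(table: SnpTable, config: FilterConfig) -> SnpTable:
    """Remove rows strictly outside the central coverage quantile interval.

    Quantiles use linear interpolation between order statistics (numpy
    default); rows on the boundary are retained.
    """
    if len(table) == 0:
        raise ValueError("cannot trim an empty table")
    q = config.tail_quantile
    if q == 0.0:
        return table.subset(np.ones(len(table), dtype=bool))
    cov = table.coverage
    lo, hi = np.quantile(cov, [q, 1.0 - q])
    out = table.subset((cov >= lo) & (cov <= hi))
    logger.info(
        "trim_coverage_quantiles: [%.2f, %.2f], %d -> %d rows", lo, hi, len(table), len(out)
    )
    return out


def filter_cascade(
    replicates: Sequence[SnpTable],
    panel: "SnpPanel",
    config: FilterConfig | None = None,
) -> tuple[SnpTable, dict]:
    """Run the full per-replicate + combined filter pipeline for one pool.

    Returns the final combined table and a report of row counts per stage.
    """
    config = config or FilterConfig()
    report: dict = {"replicates": [], "combined": {}}
    cleaned = []
    for t in replicates:
        stage = {"replicate": t.replicate, "input": len(t)}
        t1 = drop_flagged(t, panel, config)
        stage["after_drop_flagged"] = len(t1)
        t2 = filter_high_coverage(t1, config)
        stage["after_filter_high_coverage"] = len(t2)
        cleaned.append(t2)
        report["replicates"].append(stage)
    combined = combine_replicates(cleaned)
    report["combined"]["after_combine"] = len(combined)
    combined = drop_monoallelic(combined)
    report["combined"]["after_drop_monoallelic"] = len(combined)
    combined = trim_coverage_quantiles(combined, config)
    report["combined"]["after_trim_coverage_quantiles"] = len(combined)
    return combined, report
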