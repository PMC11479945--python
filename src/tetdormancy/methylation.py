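"""CpG filtering, 1 kb tiling and region-level methylation rates.

Whole-genome bisulfite data arrive as per-CpG calls (chrom, position,
methylated reads, total reads).  Downstream analyses use only calls on
autosomes covered by 10-150 reads; region- and tile-level methylation is
the *unweighted* mean of per-CpG rates, so a single high-coverage CpG
cannot dominate a tile.  Regions with fewer than ``min_cpgs`` covered
CpGs are reported with a missing (NaN) rate rather than a noisy one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SampleLabel",
    "MethylationProfile",
    "filter_cpgs",
    "pool_profiles",
    "tile_methylation",
    "region_methylation",
    "delta_methylation",
    "MOUSE_AUTOSOMES",
]

#: mm10 autosome names, the default chromosome whitelist.
MOUSE_AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 20))

_CALL_COLUMNS = ["chrom", "pos", "meth_reads", "total_reads"]


@dataclass(frozen=True)
class SampleLabel:
    """Identifies one library: genotype (WT/DKO), timepoint in hours, replicate."""

    genotype: str
    timepoint: int
    replicate: int = 1

    def __str__(self) -> str:
        return f"{self.genotype}_{self.timepoint}h_r{self.replicate}"


class MethylationProfile:
    """Per-CpG methylation calls for one sample.

    ``calls`` is a DataFrame with columns chrom, pos (0-based C position),
    meth_reads, total_reads, sorted by (chrom, pos).  ``filtered`` records
    whether the coverage/autosome filter has been applied.
    """

    def __init__(self, sample: SampleLabel, calls: pd.DataFrame, filtered: bool = False):
        missing = [c for c in _CALL_COLUMNS if c not in calls.columns]
        if missing:
            raise ValueError(f"calls missing columns: {missing}")
        calls = calls.loc[:, _CALL_COLUMNS].copy()
        if len(calls):
            if (calls["total_reads"] <= 0).any():
                raise ValueError("total_reads must be positive")
            if (calls["meth_reads"] > calls["total_reads"]).any():
                raise ValueError("meth_reads must not exceed total_reads")
            if (calls["meth_reads"] < 0).any():
                raise ValueError("meth_reads must be >= 0")
        calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.sample = sample
        self.calls = calls
        self.filtered = filtered

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def rates(self) -> np.ndarray:
        return (self.calls["meth_reads"] / self.calls["total_reads"]).to_numpy()

    @classmethod
    def read_tsv(cls, path: str | Path, sample: SampleLabel, filtered: bool = False
                 ) -> "MethylationProfile":
        """Read a bedGraph-like per-CpG TSV: chrom, start, end, meth_reads, total_reads."""
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "meth_reads", "total_reads"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "meth_reads": np.int64, "total_reads": np.int64},
        )
        df = df.rename(columns={"start": "pos"}).drop(columns=["end"])
        return cls(sample, df, filtered=filtered)

    def write_tsv(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.insert(2, "end", out["pos"] + 1)
        out.rename(columns={"pos": "start"}).to_csv(path, sep="\t", header=False, index=False)


def filter_cpgs(
    p: MethylationProfile,
    min_cov: int = 10,
    max_cov: int = 150,
    autosomes: Iterable[str] = MOUSE_AUTOSOMES,
) -> MethylationProfile:
    """Apply the coverage and autosome filter.

    Keeps calls with ``min_cov <= total_reads <= max_cov`` (both bounds
    inclusive) on the listed autosomes.  The defaults 10/150 drop
    under-covered CpGs (noisy rates) and collapsed-repeat pileups.
    """
    if p.filtered:
        raise ValueError("profile is already filtered")
    autoset = set(autosomes)
    keep = (
        (p.calls["total_reads"] >= min_cov)
        & (p.calls["total_reads"] <= max_cov)
        & p.calls["chrom"].isin(autoset)
    )
    out = p.calls.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no CpG calls survive filtering for {p.sample}", stacklevel=2)
    return MethylationProfile(p.sample, out, filtered=True)


def pool_profiles(profiles: Sequence[MethylationProfile]) -> MethylationProfile:
    """Sum read counts over replicate profiles of the same condition.

    Pooling before rate computation gives each condition a single
    deep profile; the pooled coverage is re-filtered by the caller if
    coverage bounds should apply to the pool.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    genotype = profiles[0].sample.genotype
    timepoint = profiles[0].sample.timepoint
    for p in profiles[1:]:
        if (p.sample.genotype, p.sample.timepoint) != (genotype, timepoint):
            raise ValueError("can only pool replicates of one genotype/timepoint")
    allcalls = pd.concat([p.calls for p in profiles], ignore_index=True)
    pooled = (
        allcalls.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["meth_reads", "total_reads"]
        ].sum()
    )
    label = SampleLabel(genotype, timepoint, replicate=0)
    return MethylationProfile(label, pooled, filtered=all(p.filtered for p in profiles))


def _require_filtered(p: MethylationProfile) -> None:
    if not p.filtered:
        raise ValueError("profile must be filtered first (filter_cpgs)")


def tile_methylation(
    p: MethylationProfile,
    tile_size: int = 1000,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Mean methylation over consecutive non-overlapping genomic tiles.

    Returns a DataFrame (chrom, start, end, n_cpgs, rate) with one row per
    tile containing at least one covered CpG; ``rate`` is NaN where
    ``n_cpgs < min_cpgs``.  The rate is the unweighted mean of per-CpG
    rates within the tile.
    """
    _require_filtered(p)
    if p.calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "rate"])
    df = p.calls.copy()
    df["rate"] = df["meth_reads"] / df["total_reads"]
    df["tile"] = df["pos"] // tile_size
    g = df.groupby(["chrom", "tile"], sort=True)["rate"].agg(["size", "mean"])
    out = g.reset_index()
    out["start"] = out["tile"] * tile_size
    out["end"] = out["start"] + tile_size
    out = out.rename(columns={"size": "n_cpgs", "mean": "rate"})
    out.loc[out["n_cpgs"] < min_cpgs, "rate"] = np.nan
    return out[["chrom", "start", "end", "n_cpgs", "rate"]].reset_index(drop=True)


def region_methylation(
    p: MethylationProfile,
    regions: IntervalSet,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Mean methylation over arbitrary regions (one row per input region).

    Row order follows ``regions``.  Same rate definition and ``min_cpgs``
    missing-rate rule as :func:`tile_methylation`; a region covering no
    CpGs has ``n_cpgs = 0`` and NaN rate.
    """
    _require_filtered(p)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in p.calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        rate = (sub["meth_reads"] / sub["total_reads"]).to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(rate)])
        by_chrom[chrom] = (pos, cum)
    n = np.zeros(len(regions), dtype=np.int64)
    rates = np.full(len(regions), np.nan)
    for i, iv in enumerate(regions):
        arrs = by_chrom.get(iv.chrom)
        if arrs is None:
            continue
        pos, cum = arrs
        lo = int(np.searchsorted(pos, iv.start, side="left"))
        hi = int(np.searchsorted(pos, iv.end, side="left"))
        n[i] = hi - lo
        if hi - lo >= min_cpgs:
            rates[i] = (cum[hi] - cum[lo]) / (hi - lo)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "n_cpgs": n,
            "rate": rates,
        }
    )


def delta_methylation(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-region methylation difference ``a - b``.

    ``a`` and ``b`` must describe identical region lists (same order);
    the delta is NaN wherever either side is missing.
    """
    key_cols = ["chrom", "start", "end"]
    if len(a) != len(b) or not a[key_cols].reset_index(drop=True).equals(
        b[key_cols].reset_index(drop=True)
    ):
        raise ValueError("region lists differ between the two collections")
    out = a[key_cols].reset_index(drop=True).copy()
    out["delta"] = a["rate"].to_numpy() - b["rate"].to_numpy()
    return out
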