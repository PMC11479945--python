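"""Region-level signal quantification and accessibility clustering.

CUT&Tag / ATAC coverage arrives as bedGraph tracks; regions are scored as
library-size-normalized mean per-base signal (cpm), so tracks of
different depth are directly comparable.  Accessible regions are grouped
into k ordered clusters (cluster 1 = highest mean accessibility) and a
reproducible set of methylation-gaining control tiles can be sampled to
contrast against TET-dormancy targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import GenomicInterval, IntervalSet, read_bed

__all__ = [
    "SignalTrack",
    "quantify_signal",
    "cluster_accessibility",
    "sample_control_regions",
]


class SignalTrack:
    """bedGraph-style coverage: per-chrom sorted (starts, ends, values).

    ``library_size`` is the total signal, sum(value * interval length);
    it is the denominator of the cpm normalization.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 name: str = ""):
        self.data = data
        self.name = name
        lib = 0.0
        for s, e, v in data.values():
            if (v < 0).any():
                raise ValueError("track values must be >= 0")
            lib += float(np.sum(v * (e - s)))
        self.library_size = lib

    @classmethod
    def from_bedgraph(cls, path: str | Path, name: str = "") -> "SignalTrack":
        ivs = read_bed(path, format="bedgraph", name=name or Path(path).stem)
        return cls.from_intervalset(ivs, name=ivs.name)

    @classmethod
    def from_intervalset(cls, ivs: IntervalSet, name: str = "") -> "SignalTrack":
        if ivs.scores is None:
            raise ValueError("signal track requires scores")
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        df = ivs.to_frame()
        for chrom, sub in df.groupby("chrom", sort=True):
            data[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["score"].to_numpy(float),
            )
        return cls(data, name=name)


def quantify_signal(track: SignalTrack, regions: IntervalSet) -> pd.DataFrame:
    """Score each region as cpm = mean per-base signal * 1e6 / library_size.

    Regions with no coverage (or on chromosomes absent from the track)
    get cpm 0.  Doubling every track value leaves cpm unchanged.
    """
    if track.library_size <= 0:
        raise ValueError("track library_size must be > 0")
    cpm = np.zeros(len(regions))
    # precompute cumulative signal mass per chrom for clipped-sum queries
    cums = {}
    for chrom, (s, e, v) in track.data.items():
        cums[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])
    for i, iv in enumerate(regions):
        arrs = track.data.get(iv.chrom)
        if arrs is None:
            continue
        s, e, v = arrs
        cum = cums[iv.chrom]
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        if lo >= hi:
            continue
        total = cum[hi] - cum[lo]
        total -= max(0, iv.start - int(s[lo])) * v[lo]
        total -= max(0, int(e[hi - 1]) - iv.end) * v[hi - 1]
        mean_per_base = total / len(iv)
        cpm[i] = mean_per_base * 1e6 / track.library_size
    out = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "cpm": cpm,
        }
    )
    return out


def cluster_accessibility(
    signal_matrix: np.ndarray | pd.DataFrame,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Cluster regions into k groups ordered by decreasing mean signal.

    K-means on log1p-transformed signal with ``n_init=10`` restarts and a
    fixed seed; cluster labels are then rank-ordered so that label 1 has
    the highest mean signal ("high accessibility") and label k the
    lowest.  Clusters whose centroids coincide (degenerate input, e.g.
    identical rows) are collapsed into one label.
    """
    X = np.asarray(signal_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} regions, got {X.shape[0]}")
    Xl = np.log1p(X)
    if np.allclose(Xl, Xl[0]):  # all rows identical: one degenerate cluster
        return np.ones(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(Xl)
    centroid_mean = km.cluster_centers_.mean(axis=1)
    # collapse clusters with (numerically) identical centroids
    order = np.argsort(-centroid_mean, kind="stable")
    label_of: dict[int, int] = {}
    next_label = 0
    prev_centroid = None
    for c in order:
        if prev_centroid is not None and np.allclose(
            km.cluster_centers_[c], prev_centroid, atol=1e-12
        ):
            label_of[c] = next_label
        else:
            next_label += 1
            label_of[c] = next_label
            prev_centroid = km.cluster_centers_[c]
    return np.array([label_of[c] for c in raw], dtype=int)


def sample_control_regions(
    tile_deltas: pd.DataFrame,
    n: int = 2000,
    seed: int = 0,
) -> IntervalSet:
    """Sample ``n`` tiles with positive WT methylation gain, without replacement.

    ``tile_deltas`` carries chrom/start/end/delta for genome tiles, the
    delta being WT methylation at the dormancy timepoint minus WT at 0 h.
    The sampled tiles serve as methylation-gaining control regions to
    contrast with protected targets.  Deterministic for a given seed.
    """
    eligible = tile_deltas.loc[tile_deltas["delta"] > 0].reset_index(drop=True)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} tiles with positive delta; need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    chosen = eligible.iloc[np.sort(idx)]
    return IntervalSet(
        [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in chosen.itertuples()
        ],
        name="control_regions",
    )
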