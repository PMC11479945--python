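"""Motif scanning, TF footprint scoring and motif enrichment.

A transcription-factor footprint is a local dip in transposase cut
density at bound motif occurrences: the protein shields the core motif
while cuts accumulate in the flanks.  The footprint statistic here is a
flank-vs-core depletion ratio computed on the aggregate (summed) cut
profile over all occurrences of a motif:

    score = (mean_flank - mean_core) / (mean_flank + pseudocount)

so 0 means no depletion, 0.5 means the core carries half the flank cut
density, and 1 is complete protection.  Differential footprints between
two conditions are tested against a null built by re-scoring the same
number of randomly placed same-length windows inside the same regions.

Motif enrichment at target regions versus a background uses the
upper-tail hypergeometric test on region-level motif presence, with
Benjamini-Hochberg correction across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, read_bed

__all__ = [
    "PositionWeightMatrix",
    "MotifOccurrence",
    "CutTrack",
    "FootprintResult",
    "scan_motifs",
    "footprint_score",
    "differential_footprint",
    "motif_enrichment",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


@dataclass(frozen=True)
class MotifOccurrence:
    region: GenomicInterval
    strand: str
    score: float


class PositionWeightMatrix:
    """Log-odds scoring matrix over A,C,G,T with a reporting threshold.

    ``probs`` is the L x 4 position probability matrix; log-odds are
    taken against a background distribution (uniform by default) after
    adding a small pseudo-probability to avoid -inf on zeros.
    """

    def __init__(
        self,
        name: str,
        probs: np.ndarray,
        score_threshold: float | None = None,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudo: float = 1e-3,
    ) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be L x 4 (A,C,G,T)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1")
        bg = np.asarray(background, dtype=float)
        p = (probs + pseudo) / (1 + 4 * pseudo)
        self.name = name
        self.probs = probs
        self.log_odds = np.log2(p / bg)
        self.max_score = float(self.log_odds.max(axis=1).sum())
        if score_threshold is None:
            score_threshold = 0.8 * self.max_score
        if score_threshold > self.max_score + 1e-9:
            raise ValueError("score_threshold exceeds the maximum achievable score")
        self.score_threshold = float(score_threshold)

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       score_threshold: float | None = None) -> "PositionWeightMatrix":
        """Near-deterministic PWM from a consensus string (p=0.997 per base)."""
        L = len(consensus)
        probs = np.full((L, 4), 1e-3)
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = 1 - 3e-3
        return cls(name, probs, score_threshold=score_threshold)

    @classmethod
    def read_jaspar(cls, path: str | Path, score_threshold: float | None = None
                    ) -> list["PositionWeightMatrix"]:
        """Parse JASPAR-style PFM text (``>name`` then four ``A [ ... ]`` rows)."""
        motifs: list[PositionWeightMatrix] = []
        name = None
        rows: dict[str, list[float]] = {}
        def flush() -> None:
            if name is None:
                return
            counts = np.array([rows[b] for b in _BASES], dtype=float).T
            probs = counts / counts.sum(axis=1, keepdims=True)
            motifs.append(cls(name, probs, score_threshold=score_threshold))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    name = line[1:].split()[0]
                    rows = {}
                else:
                    base = line[0].upper()
                    nums = line[1:].strip().lstrip("[").rstrip("]").split()
                    rows[base] = [float(x) for x in nums]
        flush()
        return motifs


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        code[arr == ord(b)] = i
    return code


def scan_motifs(
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    regions: IntervalSet,
) -> list[MotifOccurrence]:
    """Report every position in ``regions`` scoring >= threshold, both strands.

    ``sequences`` maps chromosome name to sequence (a pyfaidx.Fasta works
    after str() conversion; see :func:`load_fasta`).  Occurrence
    coordinates are genomic, length L, with the strand of the matching
    orientation; the same locus can be reported on both strands when both
    orientations pass the threshold.
    """
    L = len(pwm)
    lo = pwm.log_odds
    lo_rc = lo[::-1, _COMPLEMENT]  # scoring matrix for the reverse strand
    out: list[MotifOccurrence] = []
    for iv in regions:
        if iv.chrom not in sequences:
            raise KeyError(f"no sequence for chromosome {iv.chrom}")
        chrom_seq = sequences[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(f"region {iv} extends beyond sequence end ({len(chrom_seq)})")
        code = _encode(str(chrom_seq[iv.start:iv.end]))
        n = len(code) - L + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(code, L)
        valid = (windows < 4).all(axis=1)
        safe = np.minimum(windows, 3)
        pos_idx = np.arange(L)
        for strand, mat in (("+", lo), ("-", lo_rc)):
            scores = np.where(valid, mat[pos_idx, safe].sum(axis=1), -np.inf)
            for off in np.nonzero(scores >= pwm.score_threshold)[0]:
                out.append(
                    MotifOccurrence(
                        GenomicInterval(iv.chrom, iv.start + int(off), iv.start + int(off) + L),
                        strand,
                        float(scores[off]),
                    )
                )
    out.sort(key=lambda o: (o.region, o.strand))
    return out


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into chrom -> sequence strings via an indexed reader."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def occurrences_to_intervalset(occurrences: Sequence[MotifOccurrence],
                               name: str = "") -> IntervalSet:
    return IntervalSet([o.region for o in occurrences], name=name,
                       scores=[o.score for o in occurrences])


class CutTrack:
    """Dense per-base cut counts, one numpy array per chromosome.

    Positions never listed in the source bedGraph count as zero cuts.
    """

    def __init__(self, values: dict[str, np.ndarray], name: str = ""):
        self.values = values
        self.name = name
        self._flat_cache: tuple[np.ndarray, dict[str, int]] | None = None

    def _flat(self) -> tuple[np.ndarray, dict[str, int]]:
        """Concatenated per-chrom arrays plus chrom -> offset map (cached)."""
        if self._flat_cache is None:
            offsets: dict[str, int] = {}
            parts = []
            pos = 0
            for chrom in sorted(self.values):
                offsets[chrom] = pos
                parts.append(self.values[chrom])
                pos += len(self.values[chrom])
            flat = np.concatenate(parts) if parts else np.zeros(0)
            self._flat_cache = (flat, offsets)
        return self._flat_cache

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      chrom_sizes: Mapping[str, int] | None = None,
                      name: str = "") -> "CutTrack":
        ivs = read_bed(path, format="bedgraph", name=name or Path(path).stem)
        df = ivs.to_frame()
        values: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            size = chrom_sizes[chrom] if chrom_sizes else int(sub["end"].max())
            arr = np.zeros(size, dtype=float)
            for s, e, v in zip(sub["start"], sub["end"], sub["score"]):
                arr[s:e] += v
            values[chrom] = arr
        return cls(values, name=ivs.name)

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                nz = np.nonzero(arr)[0]
                if nz.size == 0:
                    continue
                # run-length encode equal-value stretches
                breaks = np.nonzero(np.diff(nz) > 1)[0]
                starts = np.concatenate([[nz[0]], nz[breaks + 1]])
                ends = np.concatenate([nz[breaks] + 1, [nz[-1] + 1]])
                for s, e in zip(starts, ends):
                    seg = arr[s:e]
                    change = np.nonzero(np.diff(seg))[0]
                    seg_starts = np.concatenate([[0], change + 1]) + s
                    seg_ends = np.concatenate([change + 1, [len(seg)]]) + s
                    for ss, ee in zip(seg_starts, seg_ends):
                        fh.write(f"{chrom}\t{ss}\t{ee}\t{arr[ss]:g}\n")


@dataclass
class FootprintResult:
    motif: str
    condition: str
    score: float
    n_occurrences: int
    z: float | None = None
    aggregate_profile: np.ndarray | None = None


def _window_matrix(track: CutTrack, occurrences: Sequence[MotifOccurrence],
                   flank: int) -> np.ndarray:
    """n_occ x (L + 2*flank) matrix of cut counts, strand-oriented."""
    L = len(occurrences[0].region)
    W = L + 2 * flank
    flat, offsets = track._flat()
    starts = np.empty(len(occurrences), dtype=np.int64)
    minus = np.zeros(len(occurrences), dtype=bool)
    for i, occ in enumerate(occurrences):
        if occ.region.chrom not in offsets:
            raise KeyError(f"cut track lacks chromosome {occ.region.chrom}")
        lo = occ.region.start - flank
        if lo < 0 or occ.region.end + flank > len(track.values[occ.region.chrom]):
            raise ValueError(f"occurrence {occ.region} +/- {flank} bp outside track")
        starts[i] = offsets[occ.region.chrom] + lo
        minus[i] = occ.strand == "-"
    out = flat[starts[:, None] + np.arange(W)]
    out[minus] = out[minus, ::-1]
    return out


def _score_profile(profile: np.ndarray, L: int, flank: int, pseudocount: float) -> float:
    core = profile[flank:flank + L]
    flanks = np.concatenate([profile[:flank], profile[flank + L:]])
    mean_flank = float(flanks.mean())
    mean_core = float(core.mean())
    return (mean_flank - mean_core) / (mean_flank + pseudocount)


def footprint_score(
    track: CutTrack,
    occurrences: Sequence[MotifOccurrence],
    flank: int = 50,
    pseudocount: float = 0.5,
    motif: str = "",
    condition: str = "",
) -> FootprintResult:
    """Aggregate flank-vs-core depletion score over motif occurrences.

    The per-position cut counts of all occurrences (strand-oriented, so
    asymmetric footprints align) are summed into one aggregate profile of
    length L + 2*flank; the score compares mean flank to mean core
    density.  A uniform profile scores exactly 0; deeper core depletion
    gives larger scores, approaching 1 at complete protection.
    """
    if not occurrences:
        raise ValueError("need at least one occurrence")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = len(occurrences[0].region)
    if any(len(o.region) != L for o in occurrences):
        raise ValueError("all occurrences must have the motif length")
    profile = _window_matrix(track, occurrences, flank).sum(axis=0)
    if profile.sum() == 0:
        warnings.warn("zero total cuts over all occurrences; score set to 0", stacklevel=2)
        score = 0.0
    else:
        score = _score_profile(profile, L, flank, pseudocount)
    return FootprintResult(motif=motif, condition=condition, score=score,
                           n_occurrences=len(occurrences), aggregate_profile=profile)


def _shuffle_starts(
    rng: np.random.Generator,
    regions: IntervalSet,
    n_shuffles: int,
    n: int,
    L: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(n_shuffles, n) arrays of (chrom index into sorted chrom list, start).

    Windows of length L are placed uniformly at random inside the given
    regions, weighted by the number of valid start positions per region.
    """
    chroms, los, his = [], [], []
    for iv in regions:
        if iv.end - L >= iv.start:
            chroms.append(iv.chrom)
            los.append(iv.start)
            his.append(iv.end - L)
    if not chroms:
        raise ValueError("no region can host a motif-length window")
    chrom_list = sorted(set(chroms))
    chrom_idx_of = {c: i for i, c in enumerate(chrom_list)}
    slot_chrom = np.array([chrom_idx_of[c] for c in chroms])
    lo_arr = np.array(los, dtype=np.int64)
    width = np.array(his, dtype=np.int64) - lo_arr + 1
    probs = width / width.sum()
    picks = rng.choice(len(lo_arr), size=(n_shuffles, n), p=probs)
    offs = (rng.random((n_shuffles, n)) * width[picks]).astype(np.int64)
    return slot_chrom[picks], lo_arr[picks] + offs, chrom_list


def _batch_deltas(
    track_a: CutTrack,
    track_b: CutTrack,
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    chrom_list: list[str],
    L: int,
    flank: int,
    pseudocount: float,
) -> np.ndarray:
    """Footprint-score deltas (a - b) for batches of window start positions."""
    W = L + 2 * flank
    win = np.arange(W)
    deltas = []
    for track in (track_a, track_b):
        flat, offsets = track._flat()
        off_vec = np.array([offsets[c] for c in chrom_list], dtype=np.int64)
        flat_starts = off_vec[chrom_idx] + starts - flank
        profiles = flat[flat_starts[..., None] + win].sum(axis=-2)
        core = profiles[..., flank:flank + L].mean(axis=-1)
        flanks = np.concatenate(
            [profiles[..., :flank], profiles[..., flank + L:]], axis=-1
        ).mean(axis=-1)
        deltas.append((flanks - core) / (flanks + pseudocount))
    return deltas[0] - deltas[1]


def differential_footprint(
    track_a: CutTrack,
    track_b: CutTrack,
    occurrences: Sequence[MotifOccurrence],
    regions: IntervalSet,
    n_shuffles: int = 100,
    seed: int = 0,
    flank: int = 50,
    pseudocount: float = 0.5,
    motif: str = "",
) -> dict:
    """Condition-A minus condition-B footprint score with a shuffled null.

    The observed delta is compared against deltas recomputed at
    ``n_shuffles`` random same-length position sets drawn within
    ``regions`` (the peak regions the occurrences live in).  The z score
    standardizes the observed delta by the null mean and sd; positive z
    means condition A has the deeper footprint.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    L = len(occurrences[0].region)
    score_a = footprint_score(track_a, occurrences, flank, pseudocount).score
    score_b = footprint_score(track_b, occurrences, flank, pseudocount).score
    delta = score_a - score_b
    rng = np.random.default_rng(seed)
    # restrict shuffle space to regions with room for the window + flanks
    host = IntervalSet(
        [GenomicInterval(iv.chrom, iv.start + flank, iv.end - flank)
         for iv in regions if len(iv) >= L + 2 * flank]
    )
    chrom_idx, starts, chrom_list = _shuffle_starts(
        rng, host, n_shuffles, len(occurrences), L
    )
    null = _batch_deltas(
        track_a, track_b, chrom_idx, starts, chrom_list, L, flank, pseudocount
    )
    null_sd = float(null.std(ddof=1))
    z = (delta - float(null.mean())) / null_sd if null_sd > 0 else 0.0
    return {
        "motif": motif,
        "delta": delta,
        "z": float(z),
        "score_a": score_a,
        "score_b": score_b,
        "null_mean": float(null.mean()),
        "null_sd": null_sd,
        "n_occurrences": len(occurrences),
        "n_shuffles": n_shuffles,
    }


def motif_enrichment(
    targets: IntervalSet,
    background: IntervalSet,
    occurrences_per_motif: Mapping[str, IntervalSet],
) -> pd.DataFrame:
    """Hypergeometric motif enrichment of targets vs a disjoint background.

    The universe is targets + background; a region "has" a motif when it
    overlaps >= 1 occurrence.  The upper-tail hypergeometric p-value asks
    whether motif-containing regions are over-represented among targets,
    and fold = (target hit rate) / (universe hit rate).  q values are
    Benjamini-Hochberg across motifs.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if targets.intersect_fraction(background, 1).any():
        raise ValueError("targets and background must be disjoint")
    N = len(targets) + len(background)
    n = len(targets)
    rows = []
    for motif_name in sorted(occurrences_per_motif):
        occ = occurrences_per_motif[motif_name]
        t_hits = int(targets.intersect_fraction(occ, 1).sum()) if len(occ) else 0
        b_hits = int(background.intersect_fraction(occ, 1).sum()) if len(occ) else 0
        K = t_hits + b_hits
        p = float(hypergeom.sf(t_hits - 1, N, K, n)) if K > 0 else 1.0
        fold = (t_hits / n) / (K / N) if K > 0 else np.nan
        rows.append({"motif": motif_name, "n_target_hits": t_hits,
                     "n_universe_hits": K, "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
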