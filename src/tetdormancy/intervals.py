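"""Genomic interval algebra and BED-family readers/writers.

All coordinates are 0-based, half-open (BED convention).  An
:class:`IntervalSet` is the universal region container consumed by every
other module: peak tracks, annotation tracks, tiles and candidate regions
all travel through it.  Chromosome names are compared by exact string
match; no "chr" prefix harmonization is attempted, so that mismatched
inputs fail loudly rather than silently returning empty overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "BedParseError",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    def expand(self, slack: int) -> "GenomicInterval":
        """Widen by ``slack`` bp on both sides, flooring the start at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.start - slack), self.end + slack, self.strand
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class BedParseError(ValueError):
    """Malformed BED-family line; message carries the 1-based line number."""


class IntervalSet:
    """An ordered, duplicate-free collection of :class:`GenomicInterval`.

    Normalization (applied on construction) sorts by ``(chrom, start, end)``
    and removes exact duplicates, keeping the first score seen for a
    duplicated span.  Scores are optional per-interval reals (e.g. a
    bedGraph value or narrowPeak signalValue).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        name: str = "",
        scores: Sequence[float] | None = None,
    ) -> None:
        ivs = list(intervals)
        if scores is not None:
            scores = list(scores)
            if len(scores) != len(ivs):
                raise ValueError("scores length must match intervals")
            order = sorted(range(len(ivs)), key=lambda i: ivs[i])
            seen: dict[GenomicInterval, int] = {}
            kept_iv: list[GenomicInterval] = []
            kept_sc: list[float] = []
            for i in order:
                key = ivs[i]
                if key not in seen:
                    seen[key] = 1
                    kept_iv.append(key)
                    kept_sc.append(scores[i])
            self.intervals: list[GenomicInterval] = kept_iv
            self.scores: np.ndarray | None = np.asarray(kept_sc, dtype=float)
        else:
            self.intervals = sorted(set(ivs))
            self.scores = None
        self.name = name
        self._merged_cache: dict[int, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<IntervalSet{label}: {len(self)} intervals>"

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )
        if self.scores is not None:
            df["score"] = self.scores
        return df

    # -- merged-array machinery ---------------------------------------------------
    def _merged(self, gap: int = 0) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chrom (starts, ends, cumulative-length) of gap-merged intervals."""
        if gap in self._merged_cache:
            return self._merged_cache[gap]
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        cur_chrom = None
        starts: list[int] = []
        ends: list[int] = []

        def flush() -> None:
            if cur_chrom is None:
                return
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(e - s)])
            out[cur_chrom] = (s, e, cum)

        for iv in self.intervals:  # already sorted
            if iv.chrom != cur_chrom:
                flush()
                cur_chrom = iv.chrom
                starts, ends = [iv.start], [iv.end]
            elif iv.start <= ends[-1] + gap:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        flush()
        self._merged_cache[gap] = out
        return out

    def merge_flatten(self, gap: int = 0) -> "IntervalSet":
        """Merge intervals closer than or equal to ``gap`` bp into single spans.

        With ``gap=0`` only touching/overlapping intervals merge, so the set
        of covered bases is preserved exactly.  The result is pairwise
        disjoint and idempotent under repeated application.
        """
        if gap < 0:
            raise ValueError("gap must be >= 0")
        merged = self._merged(gap)
        ivs = [
            GenomicInterval(chrom, int(s), int(e))
            for chrom in sorted(merged)
            for s, e in zip(*merged[chrom][:2])
        ]
        return IntervalSet(ivs, name=self.name)

    def overlap_bases(self, subject: "IntervalSet") -> np.ndarray:
        """Total overlapping bases between each of our intervals and ``subject``.

        Subject intervals are flattened first so shared bases are counted
        once.  Returns an int64 array aligned with ``self.intervals``.
        """
        merged = subject._merged(0)
        out = np.zeros(len(self), dtype=np.int64)
        for i, iv in enumerate(self.intervals):
            arrs = merged.get(iv.chrom)
            if arrs is None:
                continue
            s, e, cum = arrs
            # merged intervals fully inside [iv.start, iv.end) plus partial edges
            lo = int(np.searchsorted(e, iv.start, side="right"))
            hi = int(np.searchsorted(s, iv.end, side="left"))
            if lo >= hi:
                continue
            total = int(cum[hi] - cum[lo])
            total -= max(0, iv.start - int(s[lo]))
            total -= max(0, int(e[hi - 1]) - iv.end)
            out[i] = total
        return out

    def overlaps_within(self, subject: "IntervalSet", slack: int) -> np.ndarray:
        """Boolean per interval: does it fall within ``slack`` bp of ``subject``?

        Each query interval is expanded by ``slack`` on both sides (floored
        at 0) and tested for >= 1 bp intersection with any subject interval.
        ``slack=1000`` implements the "within 1 kb" proximity rule used for
        enhancer classification: overlap, adjacency and edge gaps strictly
        smaller than ``slack`` count; a gap of exactly ``slack`` leaves the
        expanded query merely adjacent and does not.
        """
        if slack < 0:
            raise ValueError("slack must be >= 0")
        expanded = IntervalSet([iv.expand(slack) for iv in self.intervals])
        # expansion may merge duplicates; map back through positions
        bases = {iv: b for iv, b in zip(expanded.intervals, expanded.overlap_bases(subject))}
        return np.array([bases[iv.expand(slack)] >= 1 for iv in self.intervals])

    def intersect_fraction(self, b: "IntervalSet", min_overlap: int = 1) -> np.ndarray:
        """Boolean per interval of ``self``: >= ``min_overlap`` total bases shared with ``b``."""
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        return self.overlap_bases(b) >= min_overlap

    def subtract_overlapping(self, other: "IntervalSet") -> "IntervalSet":
        """Keep intervals with zero overlap with ``other`` (whole-interval filter)."""
        keep = ~self.intersect_fraction(other, 1) if len(other) else np.ones(len(self), bool)
        scores = self.scores[keep] if self.scores is not None else None
        return IntervalSet(
            [iv for iv, k in zip(self.intervals, keep) if k], name=self.name, scores=scores
        )

    # -- I/O ----------------------------------------------------------------------
    def write_bed(self, path: str | Path) -> None:
        """Write BED3 (or BED5-with-score via name='.' when scores present)."""
        with open(path, "w") as fh:
            for i, iv in enumerate(self.intervals):
                if self.scores is not None:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{self.scores[i]:g}\t{iv.strand}\n"
                    )
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    def write_bedgraph(self, path: str | Path) -> None:
        if self.scores is None:
            raise ValueError("bedGraph output requires scores")
        with open(path, "w") as fh:
            for iv, sc in zip(self.intervals, self.scores):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{sc:g}\n")


def _parse_line(fields: list[str], lineno: int) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
    if start >= end:
        raise BedParseError(f"line {lineno}: start >= end ({start} >= {end})")
    if start < 0:
        raise BedParseError(f"line {lineno}: negative start ({start})")
    return chrom, start, end


def read_bed(path: str | Path, format: str = "bed", name: str = "") -> IntervalSet:
    """Read a BED-family file into a normalized :class:`IntervalSet`.

    Parameters
    ----------
    format
        ``"bed"`` — BED3/BED6, strand from column 6 when present, score
        from column 5;
        ``"narrowPeak"`` — ENCODE 10-column, score taken from column 7
        (signalValue);
        ``"bedgraph"`` — 4 columns, value kept as score.

    Malformed lines (start >= end, non-integer coordinates, too few
    columns) raise :class:`BedParseError` naming the 1-based line number.
    """
    if format not in {"bed", "narrowPeak", "bedgraph"}:
        raise ValueError(f"unknown format {format!r}")
    ivs: list[GenomicInterval] = []
    scores: list[float] = []
    have_scores = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = _parse_line(fields, lineno)
            strand = "."
            score = np.nan
            if format == "bedgraph":
                if len(fields) < 4:
                    raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric value") from exc
                have_scores = True
            elif format == "narrowPeak":
                if len(fields) < 10:
                    raise BedParseError(f"line {lineno}: narrowPeak needs 10 columns")
                strand = fields[5] if fields[5] in _VALID_STRANDS else "."
                try:
                    score = float(fields[6])  # signalValue
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric signalValue") from exc
                have_scores = True
            else:
                if len(fields) >= 6 and fields[5] in _VALID_STRANDS:
                    strand = fields[5]
                if len(fields) >= 5:
                    try:
                        score = float(fields[4])
                        have_scores = True
                    except ValueError:
                        pass
            ivs.append(GenomicInterval(chrom, start, end, strand))
            scores.append(score)
    if not name:
        name = Path(path).stem
    return IntervalSet(ivs, name=name, scores=scores if have_scores else None)
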