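"""Calling TET-dormancy targets and annotating them by genomic feature.

A TET-dormancy target is a region bound by TET1 and/or TET2 in wild-type
cells that (1) is protected from the methylation gain wild-type cells
experience during dormancy entry and (2) gains at least 10% methylation
in Tet1/2 double-knockout (DKO) cells relative to wild type at the same
timepoint — i.e. a site kept lowly methylated specifically by TET
activity.  Both inequalities are inclusive at the boundary and evaluated
on the [0, 1] methylation-rate scale (10% = 0.10).

This module builds the candidate universe from TET1/TET2 peak sets,
applies the two methylation criteria, classifies enhancers from
p300/histone-mark peaks, assigns each target a single genomic feature by
a priority rule, and derives canonical TFE3 targets (TFE3-bound,
non-dormancy-target regions) used as a comparison set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "TargetParams",
    "EnhancerAnnotation",
    "candidate_regions",
    "call_targets",
    "classify_enhancers",
    "annotate_targets",
    "canonical_tfe3_targets",
    "DEFAULT_FEATURE_PRIORITY",
]

DEFAULT_FEATURE_PRIORITY = ("promoter", "active_enhancer", "primed_enhancer", "L1Md")


@dataclass(frozen=True)
class TargetParams:
    """Thresholds of the target definition.

    dko_min_delta: minimum DKO-vs-WT methylation gain at ``timepoint``
    (the published criterion, >= 10%).  wt_protection_max_delta: maximum
    WT gain over 0 h for a region to count as "protected"; the published
    definition states protection without a printed threshold, so the
    same 10% magnitude is used symmetrically by default.
    """

    timepoint: int = 72
    dko_min_delta: float = 0.10
    wt_protection_max_delta: float = 0.10
    min_overlap: int = 1
    min_cpgs: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.dko_min_delta <= 1):
            raise ValueError("dko_min_delta must be in (0, 1]")
        if not (0 <= self.wt_protection_max_delta <= 1):
            raise ValueError("wt_protection_max_delta must be in [0, 1]")


@dataclass
class EnhancerAnnotation:
    """Active and primed enhancer interval sets."""

    active: IntervalSet
    primed: IntervalSet


def candidate_regions(
    tet1_peaks: IntervalSet,
    tet2_peaks: IntervalSet,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Build the candidate universe: regions bound by TET1 and/or TET2.

    Each factor's peaks are flattened within the factor; the candidate
    list is the union of both collections (exact duplicates collapse into
    one candidate).  Binding flags are re-derived by >= ``min_overlap``
    bp overlap with each factor's peaks, and the three binding classes
    (both / tet1_only / tet2_only) partition the candidates.

    Returns a DataFrame with chrom/start/end, tet1_bound, tet2_bound and
    binding_class, in normalized genomic order.
    """
    if len(tet1_peaks) == 0 and len(tet2_peaks) == 0:
        raise ValueError("both peak sets are empty")
    t1 = tet1_peaks.merge_flatten(0)
    t2 = tet2_peaks.merge_flatten(0)
    candidates = IntervalSet(list(t1) + list(t2), name="tet_candidates")
    tet1_bound = candidates.intersect_fraction(t1, min_overlap) if len(t1) else np.zeros(len(candidates), bool)
    tet2_bound = candidates.intersect_fraction(t2, min_overlap) if len(t2) else np.zeros(len(candidates), bool)
    cls = np.where(
        tet1_bound & tet2_bound, "both", np.where(tet1_bound, "tet1_only", "tet2_only")
    )
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in candidates],
            "start": [iv.start for iv in candidates],
            "end": [iv.end for iv in candidates],
            "tet1_bound": tet1_bound,
            "tet2_bound": tet2_bound,
            "binding_class": cls,
        }
    )
    return df


def _check_regions_match(candidates: pd.DataFrame, meth: pd.DataFrame, label: str) -> None:
    keys = ["chrom", "start", "end"]
    if len(candidates) != len(meth) or not candidates[keys].reset_index(drop=True).equals(
        meth[keys].reset_index(drop=True)
    ):
        raise ValueError(f"methylation collection {label} does not match candidate regions")


def call_targets(
    candidates: pd.DataFrame,
    meth_wt0: pd.DataFrame,
    meth_wt_t: pd.DataFrame,
    meth_dko_t: pd.DataFrame,
    params: TargetParams = TargetParams(),
) -> pd.DataFrame:
    """Apply the two-criterion target definition to every candidate.

    ``meth_*`` are region-methylation tables (from
    :func:`tetdormancy.methylation.region_methylation`) computed over the
    exact candidate region list: WT at 0 h, WT at the dormancy timepoint,
    and DKO at the same timepoint.

    A candidate is a target iff
    ``wt_delta = WT(t) - WT(0) <= wt_protection_max_delta`` and
    ``dko_vs_wt_delta = DKO(t) - WT(t) >= dko_min_delta`` (both inclusive).
    Candidates with missing methylation in any of the three samples are
    flagged ``undetermined`` and never called targets.
    """
    for meth, label in ((meth_wt0, "WT 0h"), (meth_wt_t, "WT t"), (meth_dko_t, "DKO t")):
        _check_regions_match(candidates, meth, label)
    wt0 = meth_wt0["rate"].to_numpy()
    wtt = meth_wt_t["rate"].to_numpy()
    dkot = meth_dko_t["rate"].to_numpy()
    wt_delta = wtt - wt0
    dko_vs_wt = dkot - wtt
    undetermined = np.isnan(wt0) | np.isnan(wtt) | np.isnan(dkot)
    is_target = (
        ~undetermined
        & (wt_delta <= params.wt_protection_max_delta)
        & (dko_vs_wt >= params.dko_min_delta)
    )
    out = candidates.reset_index(drop=True).copy()
    out["wt_delta"] = wt_delta
    out["dko_vs_wt_delta"] = dko_vs_wt
    out["undetermined"] = undetermined
    out["is_target"] = is_target
    return out


def classify_enhancers(
    p300: IntervalSet,
    h3k27ac: IntervalSet,
    h3k27me3: IntervalSet,
    h3k4me1: IntervalSet,
    slack: int = 1000,
) -> EnhancerAnnotation:
    """Chromatin-state enhancer classification with a 1 kb proximity window.

    active: p300-enriched regions within ``slack`` bp of an H3K27ac region
    and with no H3K27me3 region within ``slack`` bp.
    primed: H3K4me1-enriched regions with neither H3K27ac nor H3K27me3
    within ``slack`` bp.
    """
    if len(p300):
        near_ac = p300.overlaps_within(h3k27ac, slack) if len(h3k27ac) else np.zeros(len(p300), bool)
        near_me3 = p300.overlaps_within(h3k27me3, slack) if len(h3k27me3) else np.zeros(len(p300), bool)
        active = IntervalSet(
            [iv for iv, a, m in zip(p300, near_ac, near_me3) if a and not m],
            name="active_enhancers",
        )
    else:
        active = IntervalSet([], name="active_enhancers")
    if len(h3k4me1):
        near_ac = h3k4me1.overlaps_within(h3k27ac, slack) if len(h3k27ac) else np.zeros(len(h3k4me1), bool)
        near_me3 = h3k4me1.overlaps_within(h3k27me3, slack) if len(h3k27me3) else np.zeros(len(h3k4me1), bool)
        primed = IntervalSet(
            [iv for iv, a, m in zip(h3k4me1, near_ac, near_me3) if not a and not m],
            name="primed_enhancers",
        )
    else:
        primed = IntervalSet([], name="primed_enhancers")
    return EnhancerAnnotation(active=active, primed=primed)


def annotate_targets(
    targets: pd.DataFrame,
    promoters: IntervalSet,
    enh: EnhancerAnnotation,
    l1md: IntervalSet,
    priority: tuple[str, ...] = DEFAULT_FEATURE_PRIORITY,
) -> pd.DataFrame:
    """Assign each region a single genomic feature by priority.

    Each region gets the first feature class in ``priority`` it overlaps
    by >= 1 bp; regions overlapping none are labelled ``other``.  The
    default order promoter > active_enhancer > primed_enhancer > L1Md
    resolves multi-feature overlaps deterministically.
    """
    feature_sets = {
        "promoter": promoters,
        "active_enhancer": enh.active,
        "primed_enhancer": enh.primed,
        "L1Md": l1md,
    }
    unknown = [f for f in priority if f not in feature_sets]
    if unknown:
        raise ValueError(f"unknown feature classes in priority: {unknown}")
    regions = IntervalSet(
        [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in targets.itertuples()
        ]
    )
    # IntervalSet normalizes order; map answers back to the input row order
    hit_by_feature = {}
    for feat in priority:
        fs = feature_sets[feat]
        hits = regions.intersect_fraction(fs, 1) if len(fs) else np.zeros(len(regions), bool)
        hit_by_feature[feat] = dict(zip(regions.intervals, hits))
    features = []
    for r in targets.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        for feat in priority:
            if hit_by_feature[feat][iv]:
                features.append(feat)
                break
        else:
            features.append("other")
    out = targets.reset_index(drop=True).copy()
    out["feature"] = features
    return out


def canonical_tfe3_targets(
    tfe3_peaks_0h: IntervalSet,
    dormancy_targets: pd.DataFrame,
) -> IntervalSet:
    """TFE3 peaks (0 h) with no overlap with any called dormancy target.

    These canonical TFE3 sites are bound by TFE3 under normal growth but
    are not kept demethylated by TETs; they serve as the comparison set
    for TFE3 occupancy dynamics.
    """
    if "is_target" in dormancy_targets.columns:
        hits = dormancy_targets.loc[dormancy_targets["is_target"]]
    else:
        hits = dormancy_targets
    target_set = IntervalSet(
        [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in hits.itertuples()]
    )
    out = tfe3_peaks_0h.subtract_overlapping(target_set)
    out.name = "canonical_tfe3_targets"
    return out


def target_summary(annotated: pd.DataFrame) -> dict:
    """Counts per binding class and feature fractions among called targets."""
    tgt = annotated.loc[annotated.get("is_target", pd.Series(True, index=annotated.index))]
    n = int(len(tgt))
    by_class = tgt["binding_class"].value_counts().to_dict() if "binding_class" in tgt else {}
    fractions = (
        (tgt["feature"].value_counts() / n).round(6).to_dict() if n and "feature" in tgt else {}
    )
    return {
        "n_targets": n,
        "n_candidates": int(len(annotated)),
        "n_undetermined": int(annotated["undetermined"].sum()) if "undetermined" in annotated else 0,
        "binding_class_counts": {k: int(v) for k, v in sorted(by_class.items())},
        "feature_fractions": {k: float(v) for k, v in sorted(fractions.items())},
    }
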