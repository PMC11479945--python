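"""Target calling: candidates, thresholds, enhancer rules, annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetdormancy.intervals import GenomicInterval, IntervalSet
from tetdormancy.targets import (
    EnhancerAnnotation,
    TargetParams,
    annotate_targets,
    call_targets,
    candidate_regions,
    canonical_tfe3_targets,
    classify_enhancers,
    target_summary,
)


def ivs(*spans, name=""):
    return IntervalSet([GenomicInterval(c, s, e) for c, s, e in spans], name=name)


def meth_for(cand: pd.DataFrame, rates) -> pd.DataFrame:
    out = cand[["chrom", "start", "end"]].copy()
    out["n_cpgs"] = 8
    out["rate"] = rates
    return out


class TestCandidates:
    def test_binding_classes(self):
        tet1 = ivs(("chr1", 0, 100), ("chr1", 500, 600))
        tet2 = ivs(("chr1", 0, 100), ("chr1", 900, 1000))
        cand = candidate_regions(tet1, tet2)
        assert cand["binding_class"].tolist() == ["both", "tet1_only", "tet2_only"]

    def test_partition_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(1, 30, size=2)
            mk = lambda n: ivs(*[("chr1", int(p), int(p) + 50)
                                 for p in rng.choice(2000, n, replace=False) * 100])
            cand = candidate_regions(mk(n1), mk(n2))
            counts = cand["binding_class"].value_counts()
            assert counts.sum() == len(cand)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            candidate_regions(IntervalSet([]), IntervalSet([]))


class TestCallTargets:
    @staticmethod
    def one_candidate():
        return pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [500],
            "tet1_bound": [True], "tet2_bound": [False],
            "binding_class": ["tet1_only"],
        })

    @pytest.mark.parametrize(
        "wt0, wtt, dkot, expect",
        [
            (0.10, 0.12, 0.27, True),    # wt_delta 0.02, dko gain 0.15
            (0.10, 0.10, 0.20, True),    # dko gain exactly 0.10: inclusive
            (0.10, 0.10, 0.1999, False), # dko gain 0.0999: below threshold
            (0.10, 0.21, 0.40, False),   # wt gains 0.11: not protected
            (0.10, 0.20, 0.35, True),    # wt_delta exactly 0.10: inclusive
        ],
    )
    def test_threshold_boundaries(self, wt0, wtt, dkot, expect):
        cand = self.one_candidate()
        out = call_targets(cand, meth_for(cand, [wt0]), meth_for(cand, [wtt]),
                           meth_for(cand, [dkot]))
        assert bool(out["is_target"].iloc[0]) is expect

    def test_missing_methylation_undetermined(self):
        cand = self.one_candidate()
        out = call_targets(cand, meth_for(cand, [np.nan]), meth_for(cand, [0.1]),
                           meth_for(cand, [0.5]))
        assert bool(out["undetermined"].iloc[0])
        assert not bool(out["is_target"].iloc[0])

    def test_mismatched_regions_raise(self):
        cand = self.one_candidate()
        wrong = meth_for(cand, [0.1]).assign(start=[100], end=[600])
        with pytest.raises(ValueError):
            call_targets(cand, wrong, meth_for(cand, [0.1]), meth_for(cand, [0.3]))

    def test_matches_bruteforce_reevaluation(self):
        rng = np.random.default_rng(42)
        n = 300
        cand = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "tet1_bound": True, "tet2_bound": False, "binding_class": "tet1_only",
        })
        wt0 = meth_for(cand, rng.uniform(0, 0.6, n))
        wtt = meth_for(cand, rng.uniform(0, 0.8, n))
        dkot = meth_for(cand, rng.uniform(0, 1.0, n))
        p = TargetParams()
        out = call_targets(cand, wt0, wtt, dkot, p)
        for i in range(n):
            a, b, c = wt0["rate"][i], wtt["rate"][i], dkot["rate"][i]
            expect = (b - a <= p.wt_protection_max_delta) and (c - b >= p.dko_min_delta)
            assert bool(out["is_target"][i]) == expect

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        n = 200
        cand = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "tet1_bound": True, "tet2_bound": False, "binding_class": "tet1_only",
        })
        wt0 = meth_for(cand, rng.uniform(0, 0.5, n))
        wtt = meth_for(cand, rng.uniform(0, 0.7, n))
        dkot = meth_for(cand, rng.uniform(0, 1.0, n))
        base = call_targets(cand, wt0, wtt, dkot, TargetParams())["is_target"]
        stricter = call_targets(cand, wt0, wtt, dkot,
                                TargetParams(dko_min_delta=0.2))["is_target"]
        looser = call_targets(cand, wt0, wtt, dkot,
                              TargetParams(wt_protection_max_delta=0.3))["is_target"]
        assert not (stricter & ~base).any()   # raising dko_min never adds
        assert not (base & ~looser).any()     # raising wt_max never removes


class TestEnhancerClassifier:
    def test_active_requires_nearby_acetylation(self):
        p300 = ivs(("chr1", 1000, 1500))
        k27ac = ivs(("chr1", 2300, 2600))   # 800 bp gap
        none = IntervalSet([])
        ann = classify_enhancers(p300, k27ac, none, none)
        assert list(ann.active) == list(p300)

    def test_repressive_mark_excludes_active(self):
        p300 = ivs(("chr1", 1000, 1500))
        k27ac = ivs(("chr1", 1600, 1900))
        k27me3 = ivs(("chr1", 1200, 1300))
        ann = classify_enhancers(p300, k27ac, k27me3, IntervalSet([]))
        assert len(ann.active) == 0

    def test_primed_excluded_by_nearby_acetylation(self):
        k4me1 = ivs(("chr1", 5000, 5400))
        k27ac = ivs(("chr1", 5900, 6100))   # 500 bp gap: within 1 kb
        ann = classify_enhancers(IntervalSet([]), k27ac, IntervalSet([]), k4me1)
        assert len(ann.primed) == 0
        far = ivs(("chr1", 6500, 6700))     # 1100 bp gap: outside
        ann2 = classify_enhancers(IntervalSet([]), far, IntervalSet([]), k4me1)
        assert list(ann2.primed) == list(k4me1)

    def test_matches_bruteforce_on_random_layouts(self):
        rng = np.random.default_rng(99)
        slack = 1000
        for _ in range(100):
            def rand_set(n):
                starts = rng.integers(0, 20_000, n)
                return ivs(*[("chr1", int(s), int(s) + int(rng.integers(50, 400)))
                             for s in starts])
            p300, k27ac, k27me3, k4me1 = (rand_set(int(rng.integers(1, 8)))
                                          for _ in range(4))
            ann = classify_enhancers(p300, k27ac, k27me3, k4me1, slack)

            def near(a, bs):
                return any(a.chrom == b.chrom
                           and max(a.start - slack, 0) < b.end
                           and b.start < a.end + slack for b in bs)

            expect_active = [x for x in p300 if near(x, k27ac) and not near(x, k27me3)]
            expect_primed = [x for x in k4me1
                             if not near(x, k27ac) and not near(x, k27me3)]
            assert list(ann.active) == sorted(set(expect_active))
            assert list(ann.primed) == sorted(set(expect_primed))


class TestAnnotation:
    @staticmethod
    def targets_frame(*spans):
        return pd.DataFrame(
            [{"chrom": c, "start": s, "end": e, "is_target": True,
              "binding_class": "both", "undetermined": False}
             for c, s, e in spans]
        )

    def test_priority_resolves_multilabel(self):
        t = self.targets_frame(("chr1", 100, 200))
        enh = EnhancerAnnotation(IntervalSet([]), IntervalSet([]))
        out = annotate_targets(t, promoters=ivs(("chr1", 150, 300)), enh=enh,
                               l1md=ivs(("chr1", 100, 200)))
        assert out["feature"].iloc[0] == "promoter"

    def test_no_overlap_is_other(self):
        t = self.targets_frame(("chr1", 100, 200))
        enh = EnhancerAnnotation(IntervalSet([]), IntervalSet([]))
        out = annotate_targets(t, IntervalSet([]), enh, IntervalSet([]))
        assert out["feature"].iloc[0] == "other"

    def test_feature_fractions_sum_to_one(self):
        t = self.targets_frame(("chr1", 0, 100), ("chr1", 1000, 1100),
                               ("chr1", 2000, 2100))
        enh = EnhancerAnnotation(ivs(("chr1", 1000, 1100)), IntervalSet([]))
        out = annotate_targets(t, ivs(("chr1", 0, 100)), enh, IntervalSet([]))
        summary = target_summary(out)
        assert sum(summary["feature_fractions"].values()) == pytest.approx(1.0, abs=1e-4)
        assert summary["feature_fractions"]["promoter"] == pytest.approx(1 / 3)


class TestCanonicalTfe3:
    def test_overlapping_targets_excluded(self):
        peaks = ivs(("chr1", 0, 100), ("chr1", 1000, 1100))
        targets = pd.DataFrame({
            "chrom": ["chr1"], "start": [50], "end": [150], "is_target": [True],
        })
        out = canonical_tfe3_targets(peaks, targets)
        assert list(out) == [GenomicInterval("chr1", 1000, 1100)]

    def test_empty_target_set_returns_all_peaks(self):
        peaks = ivs(("chr1", 0, 100))
        targets = pd.DataFrame({"chrom": [], "start": [], "end": [],
                                "is_target": []})
        out = canonical_tfe3_targets(peaks, targets)
        assert list(out) == list(peaks)

    def test_output_disjoint_from_targets(self):
        rng = np.random.default_rng(3)
        peaks = ivs(*[("chr1", int(p), int(p) + 80)
                      for p in rng.choice(500, 40, replace=False) * 100])
        tgt_spans = [("chr1", int(p), int(p) + 80)
                     for p in rng.choice(500, 25, replace=False) * 100]
        targets = pd.DataFrame(
            [{"chrom": c, "start": s, "end": e, "is_target": True}
             for c, s, e in tgt_spans]
        )
        out = canonical_tfe3_targets(peaks, targets)
        tgt_ivs = ivs(*tgt_spans)
        if len(out):
            assert not out.intersect_fraction(tgt_ivs, 1).any()
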