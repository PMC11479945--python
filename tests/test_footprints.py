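"""Motif scanning, footprint scoring and hypergeometric enrichment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from tetdormancy.footprints import (
    CutTrack,
    MotifOccurrence,
    PositionWeightMatrix,
    differential_footprint,
    footprint_score,
    motif_enrichment,
    occurrences_to_intervalset,
    scan_motifs,
)
from tetdormancy.intervals import GenomicInterval, IntervalSet


def ivs(*spans):
    return IntervalSet([GenomicInterval(c, s, e) for c, s, e in spans])


class TestScan:
    def test_exact_match_found_on_both_strands(self):
        pwm = PositionWeightMatrix.from_consensus("m", "ACGT")
        seqs = {"chr1": "AAACGTAA"}
        occ = scan_motifs(seqs, pwm, ivs(("chr1", 0, 8)))
        # ACGT is its own reverse complement: one locus, both strands
        assert len(occ) == 2
        assert {o.strand for o in occ} == {"+", "-"}
        assert all(o.region == GenomicInterval("chr1", 2, 6) for o in occ)

    def test_no_match_returns_empty(self):
        pwm = PositionWeightMatrix.from_consensus("m", "CCCCCC")
        occ = scan_motifs({"chr1": "ATATATATATAT"}, pwm, ivs(("chr1", 0, 12)))
        assert occ == []

    def test_region_beyond_sequence_raises(self):
        pwm = PositionWeightMatrix.from_consensus("m", "ACGT")
        with pytest.raises(ValueError):
            scan_motifs({"chr1": "ACGTACGT"}, pwm, ivs(("chr1", 0, 100)))

    def test_asymmetric_motif_strand(self):
        pwm = PositionWeightMatrix.from_consensus("m", "AAACCC")
        occ = scan_motifs({"chr1": "TTGGGTTTAA"}, pwm, ivs(("chr1", 0, 10)))
        # GGGTTT at offset 2 is the reverse complement of AAACCC
        assert len(occ) == 1
        assert occ[0].strand == "-"
        assert occ[0].region == GenomicInterval("chr1", 2, 8)

    def test_threshold_must_be_achievable(self):
        with pytest.raises(ValueError):
            PositionWeightMatrix.from_consensus("m", "ACGT", score_threshold=1e6)

    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">MOTIF1\nA [ 10 0 0 ]\nC [ 0 10 0 ]\nG [ 0 0 10 ]\nT [ 0 0 0 ]\n"
        )
        (pwm,) = PositionWeightMatrix.read_jaspar(path)
        assert pwm.name == "MOTIF1"
        assert pwm.consensus == "ACG"


def make_occurrences(n, L=10, spacing=200, chrom="chr1", start0=100):
    return [
        MotifOccurrence(GenomicInterval(chrom, start0 + i * spacing,
                                        start0 + i * spacing + L), "+", 1.0)
        for i in range(n)
    ]


class TestFootprintScore:
    def test_uniform_profile_scores_zero(self):
        occ = make_occurrences(20)
        track = CutTrack({"chr1": np.full(6000, 3.0)})
        res = footprint_score(track, occ, flank=50)
        assert res.score == 0.0

    def test_half_depleted_core_scores_half(self):
        occ = make_occurrences(50)
        arr = np.full(12000, 100.0)
        for o in occ:
            arr[o.region.start:o.region.end] = 50.0
        res = footprint_score(CutTrack({"chr1": arr}), occ, flank=50)
        # (f - f/2) / (f + pc) with aggregate f = 5000 >> pc
        assert res.score == pytest.approx(0.5, abs=1e-3)

    def test_scaling_invariance_up_to_pseudocount(self):
        rng = np.random.default_rng(0)
        occ = make_occurrences(100)
        arr = rng.poisson(20.0, size=25_000).astype(float)
        s1 = footprint_score(CutTrack({"chr1": arr}), occ, flank=50).score
        s2 = footprint_score(CutTrack({"chr1": arr * 10}), occ, flank=50).score
        # aggregate flank means are ~2000 and ~20000; the 0.5 pseudocount
        # perturbs the ratio by < pc/mean
        assert s1 == pytest.approx(s2, abs=1e-3)

    def test_zero_cuts_warns_and_scores_zero(self):
        occ = make_occurrences(5)
        track = CutTrack({"chr1": np.zeros(2000)})
        with pytest.warns(UserWarning):
            res = footprint_score(track, occ, flank=50)
        assert res.score == 0.0

    def test_occurrence_outside_track_raises(self):
        occ = make_occurrences(1, start0=10)  # flank 50 would reach below 0
        with pytest.raises(ValueError):
            footprint_score(CutTrack({"chr1": np.ones(1000)}), occ, flank=50)


def planted_tracks(seed, n_occ=200, depth=0.5, rate=5.0, spacing=200, L=10):
    """Two Poisson tracks; condition A has a depth-planted dip at motif cores."""
    rng = np.random.default_rng(seed)
    size = 200 + n_occ * spacing
    occ = make_occurrences(n_occ, L=L, spacing=spacing)
    lam = np.full(size, rate)
    lam_b = lam.copy()
    for o in occ:
        lam[o.region.start:o.region.end] *= (1 - depth)
    a = CutTrack({"chr1": rng.poisson(lam).astype(float)})
    b = CutTrack({"chr1": rng.poisson(lam_b).astype(float)})
    host = ivs(("chr1", 60, size - 60))
    return a, b, occ, host


class TestDifferential:
    def test_identical_tracks_give_null_delta(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(5.0, size=20_000).astype(float)
        track = CutTrack({"chr1": arr})
        occ = make_occurrences(50)
        host = ivs(("chr1", 60, 19_000))
        res = differential_footprint(track, track, occ, host, n_shuffles=50, seed=2)
        assert res["delta"] == 0.0
        assert abs(res["z"]) < 1e-9

    def test_planted_footprint_detected(self):
        a, b, occ, host = planted_tracks(seed=3)
        res = differential_footprint(a, b, occ, host, n_shuffles=100, seed=4)
        assert res["delta"] > 0
        assert res["z"] > 3

    def test_occurrence_order_irrelevant(self):
        a, b, occ, host = planted_tracks(seed=5, n_occ=40)
        r1 = differential_footprint(a, b, occ, host, n_shuffles=20, seed=6)
        r2 = differential_footprint(a, b, occ[::-1], host, n_shuffles=20, seed=6)
        assert r1["delta"] == pytest.approx(r2["delta"])

    def test_too_few_shuffles_rejected(self):
        a, b, occ, host = planted_tracks(seed=7, n_occ=10)
        with pytest.raises(ValueError):
            differential_footprint(a, b, occ, host, n_shuffles=5, seed=0)

    def test_sign_recovery_of_planted_depletion(self):
        # planted 50% core depletion at 200 occurrences: the aggregate score
        # is positive in essentially every replicate simulation
        hits = 0
        for seed in range(100):
            a, _, occ, _ = planted_tracks(seed=1000 + seed)
            if footprint_score(a, occ, flank=50).score > 0:
                hits += 1
        assert hits >= 99


def enumerated_upper_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) target draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    @staticmethod
    def build(N, K, n, k):
        """Universe of N regions, first K contain the motif, targets = n
        regions of which exactly k carry the motif."""
        spans = [("chr1", i * 1000, i * 1000 + 100) for i in range(N)]
        motif_spans = [("chr1", i * 1000 + 10, i * 1000 + 20) for i in range(K)]
        target_idx = list(range(k)) + list(range(K, K + (n - k)))
        target = ivs(*[spans[i] for i in target_idx])
        background = ivs(*[spans[i] for i in range(N) if i not in target_idx])
        occ = ivs(*motif_spans) if K else IntervalSet([])
        return target, background, occ

    def test_worked_example_one_sixth(self):
        target, background, occ = self.build(N=4, K=2, n=2, k=2)
        df = motif_enrichment(target, background, {"m": occ})
        assert df["p"].iloc[0] == pytest.approx(1 / 6)
        assert df["fold"].iloc[0] == pytest.approx(2.0)

    def test_motif_everywhere_is_flat(self):
        target, background, occ = self.build(N=6, K=6, n=3, k=3)
        df = motif_enrichment(target, background, {"m": occ})
        assert df["fold"].iloc[0] == pytest.approx(1.0)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_target_hits(self):
        target, background, occ = self.build(N=6, K=2, n=2, k=0)
        df = motif_enrichment(target, background, {"m": occ})
        assert df["p"].iloc[0] == pytest.approx(1.0)
        assert df["fold"].iloc[0] == 0.0

    def test_empty_background_rejected(self):
        t = ivs(("chr1", 0, 100))
        with pytest.raises(ValueError):
            motif_enrichment(t, IntervalSet([]), {"m": t})

    def test_overlapping_sets_rejected(self):
        t = ivs(("chr1", 0, 100))
        b = ivs(("chr1", 50, 150))
        with pytest.raises(ValueError):
            motif_enrichment(t, b, {"m": IntervalSet([])})

    def test_matches_enumeration_on_small_universes(self):
        # function-level check against brute-force draws
        for N, K, n, k in [(4, 2, 2, 2), (5, 3, 2, 1), (6, 4, 3, 2),
                           (7, 3, 4, 3), (8, 5, 3, 0), (8, 2, 6, 2)]:
            target, background, occ = self.build(N, K, n, k)
            df = motif_enrichment(target, background, {"m": occ})
            assert df["p"].iloc[0] == pytest.approx(
                enumerated_upper_tail(N, K, n, k)
            ), (N, K, n, k)
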