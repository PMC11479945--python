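"""Spike-in normalization, repeat/pathway expression, contact assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetdormancy.expression import (
    CountMatrix,
    assign_contact_genes,
    normalize_counts,
    pathway_expression,
    repeat_family_expression,
    spikein_size_factors,
    summarize_contact_gene_expression,
)
from tetdormancy.intervals import GenomicInterval, IntervalSet


def matrix(counts: dict, lengths=None, spikes=None, families=None, classes=None):
    ids = list(counts)
    feats = pd.DataFrame({
        "id": ids,
        "length": [
            (lengths or {}).get(i, 1000) for i in ids
        ],
        "spike_in": [i in (spikes or set()) for i in ids],
        "repeat_family": [(families or {}).get(i, "") for i in ids],
        "repeat_class": [(classes or {}).get(i, "") for i in ids],
    })
    cdf = pd.DataFrame(counts).T
    cdf.index = ids
    return CountMatrix(feats, cdf)


class TestSizeFactors:
    def test_doubled_spikes_double_the_factor(self):
        m = matrix({
            "g1": {"s1": 50, "s2": 50},
            "ercc1": {"s1": 100, "s2": 200},
            "ercc2": {"s1": 30, "s2": 60},
        }, spikes={"ercc1", "ercc2"})
        f = spikein_size_factors(m)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        m = matrix({
            "g1": {"s1": 5, "s2": 5},
            "ercc1": {"s1": 100, "s2": 100},
            "ercc2": {"s1": 40, "s2": 40},
        }, spikes={"ercc1", "ercc2"})
        f = spikein_size_factors(m)
        assert f["s1"] == pytest.approx(f["s2"])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = {f"ercc{i}": {"s1": int(v), "s2": int(v * 1.7) + 1}
                for i, v in enumerate(rng.integers(50, 500, 20))}
        base["g1"] = {"s1": 10, "s2": 10}
        m = matrix(base, spikes={k for k in base if k.startswith("ercc")})
        f = spikein_size_factors(m)
        scaled = {k: {"s1": v["s1"] * 3, "s2": v["s2"]} for k, v in base.items()}
        m3 = matrix(scaled, spikes={k for k in base if k.startswith("ercc")})
        f3 = spikein_size_factors(m3)
        # per-row geometric means absorb c^(1/S), so the exact equivariance
        # lives in the factor *ratios*: f_s/f_t gains the full factor c
        assert (f3["s1"] / f3["s2"]) / (f["s1"] / f["s2"]) == pytest.approx(3.0)

    def test_all_zero_spikes_rejected(self):
        m = matrix({
            "g1": {"s1": 5, "s2": 5},
            "ercc1": {"s1": 0, "s2": 10},
            "ercc2": {"s1": 0, "s2": 10},
        }, spikes={"ercc1", "ercc2"})
        with pytest.raises(ValueError, match="s1"):
            spikein_size_factors(m)

    def test_recovers_simulated_factors(self):
        # 92 spike-ins, Poisson noise, true library factors 1.0 / 0.5 / 0.25
        rng = np.random.default_rng(2024)
        true = np.array([1.0, 0.5, 0.25])
        base = rng.lognormal(6.5, 0.5, size=92)
        counts = {}
        for i, b in enumerate(base):
            counts[f"ercc{i}"] = {
                f"s{j}": int(rng.poisson(b * t)) for j, t in enumerate(true)
            }
        counts["g1"] = {f"s{j}": 100 for j in range(3)}
        m = matrix(counts, spikes={k for k in counts if k.startswith("ercc")})
        f = spikein_size_factors(m).to_numpy()
        est = f / np.exp(np.mean(np.log(f)))
        want = true / np.exp(np.mean(np.log(true)))
        assert np.allclose(est, want, rtol=0.02)


class TestNormalize:
    def test_factor_two_halves_values(self):
        m = matrix({
            "g1": {"s1": 10, "s2": 10},
            "ercc1": {"s1": 100, "s2": 100},
            "ercc2": {"s1": 40, "s2": 40},
        }, spikes={"ercc1", "ercc2"})
        f = pd.Series({"s1": 1.0, "s2": 2.0})
        out = normalize_counts(m, f)
        assert out.loc["g1", "s2"] == pytest.approx(5.0)
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_spike_rows_equalized_after_tpm_normalization(self):
        rng = np.random.default_rng(5)
        counts = {f"g{i}": {"s1": int(v), "s2": int(v * 0.3) + 1}
                  for i, v in enumerate(rng.integers(100, 2000, 50))}
        for i, v in enumerate(rng.integers(100, 800, 10)):
            counts[f"ercc{i}"] = {"s1": int(v), "s2": int(v)}
        m = matrix(counts, spikes={k for k in counts if k.startswith("ercc")})
        out = normalize_counts(m, length_normalize=True)
        spikes = out.loc[m.spike_mask]
        ratios = spikes["s2"] / spikes["s1"]
        assert np.median(ratios) == pytest.approx(1.0, abs=1e-6)

    def test_global_repression_visible_after_spike_normalization(self):
        # all genes repressed 0.3x while spike-ins stay constant: the
        # spike-anchored TPM mean must drop to ~0.3x, where plain TPM stays flat
        rng = np.random.default_rng(7)
        gbase = rng.lognormal(5, 1, size=300)
        sbase = rng.lognormal(6, 0.5, size=92)
        counts = {}
        for i, b in enumerate(gbase):
            counts[f"g{i}"] = {"s1": int(rng.poisson(b)),
                               "s2": int(rng.poisson(b * 0.3))}
        for i, b in enumerate(sbase):
            counts[f"ercc{i}"] = {"s1": int(rng.poisson(b)),
                                  "s2": int(rng.poisson(b))}
        m = matrix(counts, spikes={k for k in counts if k.startswith("ercc")})
        out = normalize_counts(m, length_normalize=True)
        genes = out.loc[~m.spike_mask]
        ratio = genes["s2"].mean() / genes["s1"].mean()
        assert ratio == pytest.approx(0.3, rel=0.05)
        tpm_only = normalize_counts(m, pd.Series({"s1": 1.0, "s2": 1.0}),
                                    length_normalize=True)
        flat = tpm_only.loc[~m.spike_mask]
        assert flat["s2"].mean() / flat["s1"].mean() == pytest.approx(1.0, rel=0.02)


class TestRepeatFamilies:
    def test_members_sum_within_family(self):
        m = matrix({
            "r1": {"s1": 10}, "r2": {"s1": 20},
            "ercc1": {"s1": 100}, "ercc2": {"s1": 100},
        }, families={"r1": "L1Md_A", "r2": "L1Md_A"},
           classes={"r1": "LINE", "r2": "LINE"},
           spikes={"ercc1", "ercc2"})
        out = repeat_family_expression(m)
        factors = spikein_size_factors(m)
        expect = (10 / factors["s1"] + 20 / factors["s1"]) / 1.0  # 1 kb lengths
        assert out["s1"].iloc[0] == pytest.approx(expect)

    def test_boosted_family_has_max_ratio(self):
        rng = np.random.default_rng(11)
        fams = {"L1Md_A": "LINE", "L1Md_T": "LINE", "IAPEz": "LTR"}
        counts, families, classes = {}, {}, {}
        for fam, klass in fams.items():
            for j in range(3):
                rid = f"{fam}_m{j}"
                b = rng.integers(200, 600)
                boost = 3.0 if fam == "L1Md_T" else 1.0
                counts[rid] = {"t0": int(rng.poisson(b)),
                               "t24": int(rng.poisson(b * boost))}
                families[rid] = fam
                classes[rid] = klass
        for i in range(5):
            counts[f"ercc{i}"] = {"t0": 500, "t24": 500}
        m = matrix(counts, families=families, classes=classes,
                   spikes={k for k in counts if k.startswith("ercc")})
        out = repeat_family_expression(m)
        ratios = out["t24"] / out["t0"]
        assert ratios.idxmax()[1] == "L1Md_T"

    def test_no_repeat_rows_rejected(self):
        m = matrix({"g1": {"s1": 5}, "ercc1": {"s1": 10}, "ercc2": {"s1": 10}},
                   spikes={"ercc1", "ercc2"})
        with pytest.raises(ValueError):
            repeat_family_expression(m)


class TestPathways:
    def test_small_pathway_dropped(self):
        tpm = pd.DataFrame({"s1": np.arange(20, dtype=float)},
                           index=[f"g{i}" for i in range(20)])
        out = pathway_expression(tpm, {"tiny": [f"g{i}" for i in range(9)],
                                       "ok": [f"g{i}" for i in range(10)]})
        assert list(out.index) == ["ok"]

    def test_constant_pathway_mean(self):
        tpm = pd.DataFrame({"s1": [5.0] * 12}, index=[f"g{i}" for i in range(12)])
        out = pathway_expression(tpm, {"p": [f"g{i}" for i in range(12)]})
        assert out.loc["p", "s1"] == pytest.approx(5.0)

    def test_duplicate_genes_counted_once(self):
        tpm = pd.DataFrame({"s1": [10.0] * 10 + [0.0]},
                           index=[f"g{i}" for i in range(10)] + ["z"])
        genes = [f"g{i}" for i in range(10)] + ["z"] * 5
        out = pathway_expression(tpm, {"p": genes})
        # 10 genes at 10 plus one at 0, duplicates collapsed: mean 100/11
        assert out.loc["p", "s1"] == pytest.approx(100 / 11)


class TestContacts:
    @staticmethod
    def contacts_frame(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                           "abc_score", "contact_probability"])

    def test_contact_probability_boundary_strict(self):
        elements = IntervalSet([GenomicInterval("chr1", 0, 500)])
        c15 = self.contacts_frame([("chr1", 0, 500, "geneA", np.nan, 15.0)])
        c16 = self.contacts_frame([("chr1", 0, 500, "geneA", np.nan, 16.0)])
        assert assign_contact_genes(elements, ["L1Md"], c15).empty
        out = assign_contact_genes(elements, ["L1Md"], c16)
        assert out["gene_id"].tolist() == ["geneA"]

    def test_abc_boundary_inclusive(self):
        elements = IntervalSet([GenomicInterval("chr1", 0, 500)])
        c = self.contacts_frame([("chr1", 100, 200, "geneB", 0.02, np.nan)])
        out = assign_contact_genes(elements, ["enhancer"], c)
        assert out["gene_id"].tolist() == ["geneB"]
        low = self.contacts_frame([("chr1", 100, 200, "geneB", 0.0199, np.nan)])
        assert assign_contact_genes(elements, ["enhancer"], low).empty

    def test_cutoffs_monotone(self):
        rng = np.random.default_rng(13)
        elements = IntervalSet([GenomicInterval("chr1", i * 1000, i * 1000 + 500)
                                for i in range(30)])
        rows = [("chr1", i * 1000, i * 1000 + 500, f"gene{i}",
                 float(rng.uniform(0, 0.1)), float(rng.uniform(0, 40)))
                for i in range(30)]
        c = self.contacts_frame(rows)
        classes = ["enhancer" if i % 2 else "L1Md" for i in range(30)]
        loose = assign_contact_genes(elements, classes, c, abc_min=0.01, cp_min=5)
        tight = assign_contact_genes(elements, classes, c, abc_min=0.05, cp_min=25)
        loose_keys = set(map(tuple, loose.to_numpy()))
        tight_keys = set(map(tuple, tight.to_numpy()))
        assert tight_keys <= loose_keys

    def test_summary_and_duplicates(self):
        tpm = pd.DataFrame({"t0": [7.0, 3.0], "t72": [7.0, 1.0]},
                           index=["geneA", "geneB"])
        a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 0],
                          "end": [500, 500], "element_class": ["L1Md", "L1Md"],
                          "gene_id": ["geneA", "geneA"]})
        out = summarize_contact_gene_expression(a, tpm)
        assert out.loc["t0", "median"] == pytest.approx(7.0)
        assert out.loc["t72", "median"] == pytest.approx(7.0)

    def test_missing_genes_rejected(self):
        tpm = pd.DataFrame({"t0": [1.0]}, index=["geneZ"])
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500],
                          "element_class": ["L1Md"], "gene_id": ["geneQ"]})
        with pytest.raises(ValueError):
            summarize_contact_gene_expression(a, tpm)
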