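"""Seeded generator of a miniature dormancy-transition multi-omic dataset.

The generator emulates the statistical structure the analysis pipeline
assumes, with planted ground truth for recovery scoring:

* a small random genome (2 chromosomes) carrying TET1/TET2 "peak"
  regions laid out in feature blocks (active enhancers, primed
  enhancers, promoters, L1Md repeats, unannotated), each bound region
  containing an exact embedded motif instance;
* beta-binomial per-CpG methylation per genotype x timepoint x
  replicate: the whole genome gains ``background_gain`` methylation by
  72 h in *both* genotypes (the global, TET-independent rise), while
  planted target regions stay low in wild type and gain
  ``planted_dko_delta`` only in the double knockout — precisely the
  signature the target caller is built to find;
* per-base transposase cut tracks with a multiplicative dip over motif
  cores in conditions where the factor is bound (a plantable footprint);
* an RNA count matrix of genes, repeat consensi and constant ERCC-style
  spike-ins, with global repression over time and one transiently
  boosted repeat family.

All randomness flows from one master seed through named substreams, so
every output file is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .methylation import SampleLabel

__all__ = ["SimConfig", "SimTruth", "simulate_dataset",
           "simulate_genome", "simulate_methylation",
           "simulate_cut_tracks", "simulate_counts"]

# substream indices for the master seed
_STREAMS = {
    "genome": 0, "layout": 1, "methylation": 2, "cuts": 3, "counts": 4,
    "contacts": 5,
}

_FEATURES = ("promoter", "active_enhancer", "primed_enhancer", "L1Md")


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream], extra]))


@dataclass
class SimConfig:
    """Study conditions of the synthetic dormancy-transition dataset."""

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    cpg_spacing_mean: float = 100.0
    # TET binding
    n_tet1_peaks: int = 1400
    n_tet2_peaks: int = 1000
    frac_cobound: float = 0.4          # of min(n_tet1, n_tet2), emitted in both files
    peak_width: int = 500
    min_cpgs_per_peak: int = 8
    # planted targets
    n_planted_targets: int = 200
    planted_dko_delta: float = 0.25
    planted_wt_delta_sd: float = 0.02
    background_gain: float = 0.15      # global WT methylation rise by 72 h
    baseline_meth: float = 0.15
    # WGBS noise
    coverage_mean: float = 30.0
    dispersion: float = 0.05           # beta-binomial overdispersion rho
    # annotation element totals (candidate-colocated + standalone)
    n_enhancers: int = 240             # active enhancers
    n_primed_enhancers: int = 300
    n_promoters: int = 300
    n_l1md: int = 760
    n_decoy_p300: int = 40             # p300 sites with H3K27me3 (never active)
    n_tfe3_standalone: int = 150
    n_tfe3_on_targets: int = 100
    # fraction of candidates colocated with each feature class
    feature_fractions: dict = field(default_factory=lambda: {
        "promoter": 0.12, "active_enhancer": 0.10,
        "primed_enhancer": 0.13, "L1Md": 0.33,
    })
    # footprinting
    motif_consensus: str = "GTCACGTGAC"
    footprint_depth: float = 0.5
    cut_rate: float = 5.0              # Poisson cuts per base in covered windows
    n_footprint_regions: int = 300
    footprint_window: int = 60         # coverage margin around each peak
    # expression
    n_genes: int = 500
    n_spikeins: int = 92
    repression_factors: dict = field(default_factory=lambda: {
        0: 1.0, 24: 0.6, 72: 0.4, 144: 0.3,
    })
    library_factor_sd: float = 0.15
    boost_family: str = "L1Md_A"
    boost_factor: float = 3.0
    boost_timepoint: int = 24
    # design
    timepoints: tuple = (0, 24, 72, 144)
    replicates: int = 2
    genotypes: tuple = ("WT", "DKO")
    target_timepoint: int = 72

    def __post_init__(self) -> None:
        n_candidates = self.n_candidates
        if self.n_planted_targets > n_candidates:
            raise ValueError("more planted targets than candidate peaks")
        if not (0 <= self.footprint_depth <= 1):
            raise ValueError("footprint_depth must be in [0, 1]")
        if not (0 < self.dispersion < 1):
            raise ValueError("dispersion must be in (0, 1)")

    @property
    def n_cobound(self) -> int:
        return round(self.frac_cobound * min(self.n_tet1_peaks, self.n_tet2_peaks))

    @property
    def n_candidates(self) -> int:
        return self.n_tet1_peaks + self.n_tet2_peaks - self.n_cobound

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=list)


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside every dataset."""

    candidates: pd.DataFrame          # chrom,start,end,binding_class,feature,is_target,...
    chrom_sizes: dict
    motif_consensus: str
    footprint_bound_conditions: list
    footprint_depth: float
    library_factors: dict             # sample -> factor
    repression_factors: dict
    boost_family: str
    annotation_files: dict

    def target_set(self) -> IntervalSet:
        hit = self.candidates.loc[self.candidates["is_target"]]
        return IntervalSet(
            [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in hit.itertuples()],
            name="planted_targets",
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "candidates": json.loads(
                self.candidates.to_json(orient="records")
            ),
            "chrom_sizes": self.chrom_sizes,
            "motif_consensus": self.motif_consensus,
            "footprint_bound_conditions": self.footprint_bound_conditions,
            "footprint_depth": self.footprint_depth,
            "library_factors": self.library_factors,
            "repression_factors": {str(k): v for k, v in self.repression_factors.items()},
            "boost_family": self.boost_family,
            "annotation_files": self.annotation_files,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            candidates=pd.DataFrame(payload["candidates"]),
            chrom_sizes=payload["chrom_sizes"],
            motif_consensus=payload["motif_consensus"],
            footprint_bound_conditions=payload["footprint_bound_conditions"],
            footprint_depth=payload["footprint_depth"],
            library_factors=payload["library_factors"],
            repression_factors={int(k): v for k, v in payload["repression_factors"].items()},
            boost_family=payload["boost_family"],
            annotation_files=payload["annotation_files"],
        )


# --------------------------------------------------------------------------- layout


def _place_blocks(cfg: SimConfig) -> dict:
    """Deterministic block layout of feature sites along the genome.

    Sites of one kind are laid out contiguously at a fixed pitch, with a
    2 kb guard gap between blocks so the 1 kb proximity rules of the
    enhancer classifier cannot leak across feature classes.  Raises when
    the demanded features exceed genome capacity.
    """
    n_cand = cfg.n_candidates
    colocated = {}
    for feat in _FEATURES:
        want = round(cfg.feature_fractions.get(feat, 0.0) * n_cand)
        total = {"promoter": cfg.n_promoters, "active_enhancer": cfg.n_enhancers,
                 "primed_enhancer": cfg.n_primed_enhancers, "L1Md": cfg.n_l1md}[feat]
        colocated[feat] = min(want, total)
    standalone = {
        "promoter": cfg.n_promoters - colocated["promoter"],
        "active_enhancer": cfg.n_enhancers - colocated["active_enhancer"],
        "primed_enhancer": cfg.n_primed_enhancers - colocated["primed_enhancer"],
        "L1Md": cfg.n_l1md - colocated["L1Md"],
    }
    n_other = n_cand - sum(colocated.values())
    if n_other < 0:
        raise ValueError("feature_fractions demand more colocated features than candidates")

    w = cfg.peak_width
    blocks = [
        # (kind, count, site_span, pitch)
        ("cand_active", colocated["active_enhancer"], w + 500, w + 700),
        ("alone_active", standalone["active_enhancer"], w + 500, w + 700),
        ("guard", 1, 0, 2000),
        ("decoy_p300", cfg.n_decoy_p300, w, w + 300),
        ("guard", 1, 0, 2000),
        ("cand_primed", colocated["primed_enhancer"], w, w + 300),
        ("alone_primed", standalone["primed_enhancer"], w, w + 300),
        ("guard", 1, 0, 2000),
        ("cand_promoter", colocated["promoter"], w, w + 200),
        ("alone_promoter", standalone["promoter"], w, w + 200),
        ("cand_l1md", colocated["L1Md"], w, w + 200),
        ("alone_l1md", standalone["L1Md"], w, w + 200),
        ("cand_other", n_other, w, w + 200),
        ("alone_tfe3", cfg.n_tfe3_standalone, w, w + 200),
    ]
    sites: dict[str, list[tuple[str, int]]] = {}
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    ci, pos = 0, 1000
    for kind, count, span, pitch in blocks:
        if kind == "guard":
            pos += pitch
            continue
        placed = []
        for _ in range(count):
            if pos + pitch > cfg.chrom_length - 1000:
                ci += 1
                pos = 1000
                if ci >= cfg.n_chrom:
                    raise ValueError("feature demand exceeds genome capacity")
            placed.append((chrom_names[ci], pos))
            pos += pitch
        sites[kind] = placed
    return sites


def simulate_genome(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate the genome FASTA, peak/annotation BEDs, CpG layout and truth.

    Writes genome.fa, peaks_tet1/tet2/tfe3.bed, the four chromatin-mark
    BEDs, annot_promoters/l1md.bed, footprint_regions.bed, cpg_positions.tsv
    and returns the populated :class:`SimTruth` (without expression truth,
    which :func:`simulate_counts` fills in).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg.seed, "genome")
    lay_rng = _rng(cfg.seed, "layout")
    sites = _place_blocks(cfg)
    w = cfg.peak_width

    # ---- candidate table -----------------------------------------------------
    rows = []
    for kind, feat in (
        ("cand_active", "active_enhancer"), ("cand_primed", "primed_enhancer"),
        ("cand_promoter", "promoter"), ("cand_l1md", "L1Md"), ("cand_other", "other"),
    ):
        for chrom, pos in sites.get(kind, []):
            rows.append({"chrom": chrom, "start": pos, "end": pos + w, "feature": feat})
    cand = pd.DataFrame(rows)
    n_cand = len(cand)

    # binding classes: a random partition into both / tet1_only / tet2_only
    n_both = cfg.n_cobound
    n_t1 = cfg.n_tet1_peaks - n_both
    classes = np.array(
        ["both"] * n_both + ["tet1_only"] * n_t1
        + ["tet2_only"] * (n_cand - n_both - n_t1)
    )
    lay_rng.shuffle(classes)
    cand["binding_class"] = classes

    # planted targets: uniform over candidates
    target_idx = lay_rng.choice(n_cand, size=cfg.n_planted_targets, replace=False)
    is_target = np.zeros(n_cand, bool)
    is_target[target_idx] = True
    cand["is_target"] = is_target
    cand["baseline_meth"] = lay_rng.uniform(0.05, 0.25, size=n_cand)
    wt_drift = lay_rng.normal(0.0, cfg.planted_wt_delta_sd, size=n_cand)
    cand["true_wt_delta"] = np.where(is_target, wt_drift, cfg.background_gain)
    cand["true_dko_delta"] = np.where(  # DKO(t) - WT(t) at the target timepoint
        is_target, cfg.planted_dko_delta - wt_drift, 0.0
    )
    cand = cand.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # ---- FASTA with embedded motif instances ----------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    motif = np.frombuffer(cfg.motif_consensus.encode(), dtype="S1")
    seqs: dict[str, np.ndarray] = {
        c: bases[rng.integers(0, 4, size=cfg.chrom_length)] for c in chrom_names
    }
    motif_starts = []
    for r in cand.itertuples():
        mstart = r.start + (w - len(motif)) // 2
        seqs[r.chrom][mstart:mstart + len(motif)] = motif
        motif_starts.append(mstart)
    cand["motif_start"] = motif_starts
    with open(outdir / "genome.fa", "w") as fh:
        for c in chrom_names:
            fh.write(f">{c}\n")
            raw = seqs[c].tobytes().decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i:i + 80] + "\n")

    # ---- peak and annotation BEDs ---------------------------------------------
    def ivset(df: pd.DataFrame, name: str) -> IntervalSet:
        return IntervalSet(
            [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()],
            name=name,
        )

    tet1 = cand.loc[cand["binding_class"].isin(["both", "tet1_only"])]
    tet2 = cand.loc[cand["binding_class"].isin(["both", "tet2_only"])]
    ivset(tet1, "tet1").write_bed(outdir / "peaks_tet1.bed")
    ivset(tet2, "tet2").write_bed(outdir / "peaks_tet2.bed")

    def block_ivs(kind: str, width: int, offset: int = 0) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, pos + offset, pos + offset + width)
            for chrom, pos in sites.get(kind, [])
        ]

    # active enhancers: p300 at the site, H3K27ac 300 bp downstream of the span
    p300 = block_ivs("cand_active", w) + block_ivs("alone_active", w) \
        + block_ivs("decoy_p300", w)
    k27ac = block_ivs("cand_active", 200, offset=w + 300) \
        + block_ivs("alone_active", 200, offset=w + 300)
    k27me3 = block_ivs("decoy_p300", w)  # decoys carry the repressive mark
    k4me1 = block_ivs("cand_primed", w) + block_ivs("alone_primed", w)
    IntervalSet(p300, name="p300").write_bed(outdir / "peaks_p300.bed")
    IntervalSet(k27ac, name="h3k27ac").write_bed(outdir / "peaks_h3k27ac.bed")
    IntervalSet(k27me3, name="h3k27me3").write_bed(outdir / "peaks_h3k27me3.bed")
    IntervalSet(k4me1, name="h3k4me1").write_bed(outdir / "peaks_h3k4me1.bed")

    promoters = block_ivs("cand_promoter", w) + block_ivs("alone_promoter", w)
    l1md = block_ivs("cand_l1md", w) + block_ivs("alone_l1md", w)
    IntervalSet(promoters, name="promoters").write_bed(outdir / "annot_promoters.bed")
    IntervalSet(l1md, name="l1md").write_bed(outdir / "annot_l1md.bed")

    # TFE3: standalone sites plus a subset of planted targets
    tfe3 = block_ivs("alone_tfe3", w)
    tgt_rows = cand.loc[cand["is_target"]]
    n_on = min(cfg.n_tfe3_on_targets, len(tgt_rows))
    pick = lay_rng.choice(len(tgt_rows), size=n_on, replace=False)
    tfe3 += [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in tgt_rows.iloc[np.sort(pick)].itertuples()
    ]
    IntervalSet(tfe3, name="tfe3").write_bed(outdir / "peaks_tfe3.bed")

    # footprint coverage universe: the first n covered candidate peaks
    fp = cand.iloc[: cfg.n_footprint_regions]
    ivset(fp, "footprint_regions").write_bed(outdir / "footprint_regions.bed")

    # ---- CpG positions ---------------------------------------------------------
    cpg = {}
    for c in chrom_names:
        gaps = rng.exponential(cfg.cpg_spacing_mean, size=int(cfg.chrom_length / cfg.cpg_spacing_mean * 1.3))
        pos = np.cumsum(np.maximum(2, gaps.astype(np.int64))) + 100
        pos = pos[pos < cfg.chrom_length - 100]
        cpg[c] = pos
    # guarantee min_cpgs_per_peak inside every candidate peak
    extra = {c: [] for c in chrom_names}
    for r in cand.itertuples():
        planted = np.linspace(r.start + 10, r.end - 10, cfg.min_cpgs_per_peak).astype(np.int64)
        extra[r.chrom].append(planted)
    cpg_final = {}
    for c in chrom_names:
        allpos = np.concatenate([cpg[c]] + extra[c]) if extra[c] else cpg[c]
        cpg_final[c] = np.unique(allpos)
    with open(outdir / "cpg_positions.tsv", "w") as fh:
        for c in chrom_names:
            for p in cpg_final[c]:
                fh.write(f"{c}\t{p}\n")

    truth = SimTruth(
        candidates=cand,
        chrom_sizes={c: cfg.chrom_length for c in chrom_names},
        motif_consensus=cfg.motif_consensus,
        footprint_bound_conditions=[f"WT_{cfg.target_timepoint}"],
        footprint_depth=cfg.footprint_depth,
        library_factors={},
        repression_factors=dict(cfg.repression_factors),
        boost_family=cfg.boost_family,
        annotation_files={
            "tet1": "peaks_tet1.bed", "tet2": "peaks_tet2.bed", "tfe3": "peaks_tfe3.bed",
            "p300": "peaks_p300.bed", "h3k27ac": "peaks_h3k27ac.bed",
            "h3k27me3": "peaks_h3k27me3.bed", "h3k4me1": "peaks_h3k4me1.bed",
            "promoters": "annot_promoters.bed", "l1md": "annot_l1md.bed",
            "footprint_regions": "footprint_regions.bed",
        },
    )
    truth._cpg_positions = cpg_final  # cached for the methylation stage
    return truth


# ------------------------------------------------------------------- methylation


def _ramp(t: int, target_t: int) -> float:
    """Fraction of the methylation gain realized by time t (full at target_t)."""
    return min(t, target_t) / target_t


def simulate_methylation(cfg: SimConfig, truth: SimTruth, outdir: str | Path) -> list[Path]:
    """Write per-sample CpG call TSVs (chrom, start, end, meth, total).

    Region means: background CpGs sit at ``baseline_meth`` and gain
    ``background_gain`` by the target timepoint in both genotypes;
    candidate-peak CpGs use the candidate's baseline; planted targets
    stay flat in WT (small drift) and gain ``planted_dko_delta`` in DKO.
    Per-CpG rates are beta-distributed around the region mean with
    overdispersion ``dispersion``; coverage is Poisson and counts
    binomial.
    """
    outdir = Path(outdir)
    cpg = getattr(truth, "_cpg_positions", None)
    if cpg is None:
        cpg = _read_cpg_positions(outdir / "cpg_positions.tsv")
    cand = truth.candidates
    s = (1 - cfg.dispersion) / cfg.dispersion

    # map every CpG to a candidate region (-1 = background), vectorized per chrom
    chrom_order = sorted(cpg)
    maps = {}
    for c in chrom_order:
        sub = cand.loc[cand["chrom"] == c]
        if sub.empty:
            maps[c] = np.full(len(cpg[c]), -1, dtype=np.int64)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, cpg[c], side="right") - 1
        inside = (idx >= 0) & (cpg[c] < ends[np.maximum(idx, 0)])
        region = np.where(inside, sub.index.to_numpy()[np.maximum(idx, 0)], -1)
        maps[c] = region

    base = np.concatenate([
        np.where(maps[c] >= 0,
                 cand["baseline_meth"].reindex(np.maximum(maps[c], 0)).to_numpy(),
                 cfg.baseline_meth)
        for c in chrom_order
    ])
    region_flat = np.concatenate([maps[c] for c in chrom_order])
    is_tgt = np.zeros(len(region_flat), bool)
    in_cand = region_flat >= 0
    is_tgt[in_cand] = cand["is_target"].reindex(region_flat[in_cand]).to_numpy()
    wt_drift = np.zeros(len(region_flat))
    wt_drift[in_cand] = cand["true_wt_delta"].reindex(region_flat[in_cand]).to_numpy()
    # for non-target candidates true_wt_delta == background_gain already

    paths = []
    files = {}
    for gi, g in enumerate(cfg.genotypes):
        for ti, t in enumerate(cfg.timepoints):
            ramp = _ramp(t, cfg.target_timepoint)
            if g == "WT":
                mu = np.where(is_tgt, base + wt_drift * ramp, base + cfg.background_gain * ramp)
            else:
                mu = np.where(is_tgt, base + cfg.planted_dko_delta * ramp,
                              base + cfg.background_gain * ramp)
            mu = np.clip(mu, 0.01, 0.99)
            for r in range(1, cfg.replicates + 1):
                sub = (gi * len(cfg.timepoints) + ti) * (cfg.replicates + 1) + r
                rng = _rng(cfg.seed, "methylation", extra=sub)
                rates = rng.beta(mu * s, (1 - mu) * s)
                cov = np.maximum(1, rng.poisson(cfg.coverage_mean, size=len(mu)))
                meth = rng.binomial(cov, rates)
                label = SampleLabel(g, t, r)
                path = outdir / f"meth_{label}.tsv"
                out = pd.DataFrame({
                    "chrom": np.concatenate([[c] * len(cpg[c]) for c in chrom_order]),
                    "start": np.concatenate([cpg[c] for c in chrom_order]),
                })
                out["end"] = out["start"] + 1
                out["meth"] = meth
                out["total"] = cov
                out.to_csv(path, sep="\t", header=False, index=False)
                paths.append(path)
                files[str(label)] = path.name
    truth.annotation_files["methylation"] = files
    return paths


def _read_cpg_positions(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"])
    return {c: sub["pos"].to_numpy() for c, sub in df.groupby("chrom")}


# --------------------------------------------------------------------- cut tracks


def simulate_cut_tracks(cfg: SimConfig, truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write per-condition bedGraph cut tracks over the footprint regions.

    Conditions are WT and DKO at the target timepoint.  Cut counts are
    Poisson(``cut_rate``) per base over each covered window (peak +/-
    ``footprint_window``); in bound conditions the expected rate over
    each embedded motif core is multiplied by ``1 - footprint_depth``.
    """
    outdir = Path(outdir)
    fp = truth.candidates.iloc[: cfg.n_footprint_regions]
    L = len(cfg.motif_consensus)
    out_paths = {}
    conditions = [f"WT_{cfg.target_timepoint}", f"DKO_{cfg.target_timepoint}"]
    for k, condition in enumerate(conditions):
        bound = condition in truth.footprint_bound_conditions
        rng = _rng(cfg.seed, "cuts", extra=k)
        lines = []
        for r in fp.itertuples():
            lo = r.start - cfg.footprint_window
            hi = r.end + cfg.footprint_window
            lam = np.full(hi - lo, cfg.cut_rate)
            if bound and cfg.footprint_depth > 0:
                mo = r.motif_start - lo
                lam[mo:mo + L] *= (1 - cfg.footprint_depth)
            vals = rng.poisson(lam)
            pos = np.arange(lo, hi)
            nz = vals > 0
            for p, v in zip(pos[nz], vals[nz]):
                lines.append(f"{r.chrom}\t{p}\t{p + 1}\t{v}")
        path = outdir / f"cuts_{condition}.bedgraph"
        path.write_text("\n".join(lines) + "\n")
        out_paths[condition] = path
    truth.annotation_files["cut_tracks"] = {c: p.name for c, p in out_paths.items()}
    return out_paths


# ------------------------------------------------------------------------ counts


_REPEAT_FAMILIES = {
    "L1Md_A": ("LINE", 3), "L1Md_T": ("LINE", 3), "L1Md_Gf": ("LINE", 2),
    "L1Md_F": ("LINE", 4), "IAPEz": ("LTR", 3), "MERVL": ("LTR", 2),
}


def simulate_counts(cfg: SimConfig, truth: SimTruth, outdir: str | Path
                    ) -> tuple[Path, Path]:
    """Write the counts TSV and feature sidecar; record truth factors.

    Gene counts are Poisson(baseline x repression(t) x library factor);
    spike-ins are Poisson(constant x library factor), so they track cell
    number, not transcriptome size.  One repeat family receives a
    transient boost at ``boost_timepoint`` in wild type.
    """
    outdir = Path(outdir)
    rng = _rng(cfg.seed, "counts")
    gene_ids = [f"gene{i:04d}" for i in range(1, cfg.n_genes + 1)]
    gene_len = rng.integers(500, 5000, size=cfg.n_genes)
    gene_base = rng.lognormal(mean=4.0, sigma=1.0, size=cfg.n_genes)
    spike_ids = [f"ERCC-{i:05d}" for i in range(1, cfg.n_spikeins + 1)]
    spike_len = rng.integers(250, 2000, size=cfg.n_spikeins)
    spike_base = rng.lognormal(mean=5.0, sigma=0.8, size=cfg.n_spikeins)
    rep_rows = []
    for fam, (klass, n_members) in _REPEAT_FAMILIES.items():
        for m in range(1, n_members + 1):
            rep_rows.append((f"{fam}_m{m}", klass, fam))
    rep_ids = [r[0] for r in rep_rows]
    rep_len = rng.integers(4000, 7000, size=len(rep_rows))
    rep_base = rng.lognormal(mean=3.5, sigma=0.7, size=len(rep_rows))

    samples = [
        SampleLabel(g, t, r)
        for g in cfg.genotypes for t in cfg.timepoints
        for r in range(1, cfg.replicates + 1)
    ]
    lib = rng.lognormal(mean=0.0, sigma=cfg.library_factor_sd, size=len(samples))
    counts = {}
    for j, lab in enumerate(samples):
        rep_factor = cfg.repression_factors[lab.timepoint]
        gene_mu = gene_base * rep_factor * lib[j]
        rmult = np.ones(len(rep_rows))
        for i, (_, _, fam) in enumerate(rep_rows):
            boost = (
                cfg.boost_factor
                if fam == cfg.boost_family and lab.timepoint == cfg.boost_timepoint
                and lab.genotype == "WT" else 1.0
            )
            rmult[i] = boost
        rep_mu = rep_base * rep_factor * rmult * lib[j]
        spike_mu = spike_base * lib[j]
        counts[str(lab)] = np.concatenate([
            rng.poisson(gene_mu), rng.poisson(rep_mu), rng.poisson(spike_mu),
        ])
    features = pd.DataFrame({
        "id": gene_ids + rep_ids + spike_ids,
        "length": np.concatenate([gene_len, rep_len, spike_len]),
        "spike_in": [False] * (cfg.n_genes + len(rep_rows)) + [True] * cfg.n_spikeins,
        "repeat_family": [""] * cfg.n_genes + [r[2] for r in rep_rows] + [""] * cfg.n_spikeins,
        "repeat_class": [""] * cfg.n_genes + [r[1] for r in rep_rows] + [""] * cfg.n_spikeins,
    })
    cmat = pd.DataFrame(counts, index=features["id"])
    counts_path = outdir / "counts.tsv"
    features_path = outdir / "features.tsv"
    cmat.to_csv(counts_path, sep="\t", index_label="id")
    features.to_csv(features_path, sep="\t", index=False)
    truth.library_factors = {str(lab): float(f) for lab, f in zip(samples, lib)}
    return counts_path, features_path


# ---------------------------------------------------------------------- contacts


def simulate_contacts(cfg: SimConfig, truth: SimTruth, outdir: str | Path) -> Path:
    """Element-gene contact records for active-enhancer and L1Md candidates."""
    outdir = Path(outdir)
    rng = _rng(cfg.seed, "contacts")
    cand = truth.candidates
    rows = []
    for r in cand.itertuples():
        if r.feature == "active_enhancer":
            gene = f"gene{rng.integers(1, cfg.n_genes + 1):04d}"
            rows.append((r.chrom, r.start, r.end, gene,
                         round(float(rng.uniform(0.0, 0.1)), 4), ""))
        elif r.feature == "L1Md":
            gene = f"gene{rng.integers(1, cfg.n_genes + 1):04d}"
            rows.append((r.chrom, r.start, r.end, gene, "",
                         round(float(rng.uniform(2.0, 40.0)), 2)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                     "abc_score", "contact_probability"])
    path = outdir / "contacts.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------- top level


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate the full synthetic dataset under ``outdir``.

    Writes genome, peaks, annotations, methylation, cut tracks, counts,
    contacts, the config echo (simconfig.json) and ground truth
    (truth.json).  Returns the :class:`SimTruth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_genome(cfg, outdir)
    simulate_methylation(cfg, truth, outdir)
    simulate_cut_tracks(cfg, truth, outdir)
    simulate_counts(cfg, truth, outdir)
    simulate_contacts(cfg, truth, outdir)
    cfg.to_json(outdir / "simconfig.json")
    truth.to_json(outdir / "truth.json")
    return truth
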