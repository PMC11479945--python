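"""End-to-end orchestration: config in, target calls and reports out.

The pipeline wires the library modules together in dependency order:

    filter CpGs -> tile -> candidate regions -> call targets -> annotate
    -> control regions -> footprints -> motif enrichment -> spike-in
    normalization -> contact-gene assignment

and writes fixed-name outputs (targets.tsv/.bed, controls.bed,
footprints.tsv, enrichment.tsv, contacts_assigned.tsv, normalized_tpm.tsv,
report.json) under the configured output directory.  Reruns with the same
config and inputs produce byte-identical reports: every random step takes
an explicit seed recorded in the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    CountMatrix,
    assign_contact_genes,
    normalize_counts,
    read_contacts,
    repeat_family_expression,
    spikein_size_factors,
    summarize_contact_gene_expression,
)
from .footprints import (
    CutTrack,
    PositionWeightMatrix,
    differential_footprint,
    footprint_score,
    load_fasta,
    motif_enrichment,
    occurrences_to_intervalset,
    scan_motifs,
)
from .intervals import GenomicInterval, IntervalSet, read_bed
from .methylation import (
    MethylationProfile,
    SampleLabel,
    delta_methylation,
    filter_cpgs,
    pool_profiles,
    region_methylation,
    tile_methylation,
)
from .signal import sample_control_regions
from .targets import (
    EnhancerAnnotation,
    TargetParams,
    annotate_targets,
    call_targets,
    candidate_regions,
    canonical_tfe3_targets,
    classify_enhancers,
    target_summary,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "config_from_sim_dir"]


class ConfigError(ValueError):
    """Raised before any computation when the configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``methylation`` lists per-sample call files with genotype, timepoint
    and replicate; ``peaks`` maps factor/mark names to BED paths.  All
    relative paths resolve against ``base_dir``.
    """

    methylation: list = field(default_factory=list)
    peaks: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    cut_tracks: dict = field(default_factory=dict)
    footprint_regions: str = ""
    fasta: str = ""
    motifs: list = field(default_factory=list)   # [{"name":..., "consensus":...}]
    counts: dict = field(default_factory=dict)   # {"matrix":..., "features":...}
    contacts: str = ""
    truth: str = ""                              # optional truth.json for scoring
    outdir: str = "run"
    base_dir: str = "."
    # parameters
    target_params: dict = field(default_factory=dict)
    min_cov: int = 10
    max_cov: int = 150
    autosomes: list = field(default_factory=lambda: [f"chr{i}" for i in range(1, 20)])
    tile_size: int = 1000
    control_n: int = 2000
    control_seed: int = 1
    footprint_flank: int = 50
    footprint_n_shuffles: int = 100
    footprint_seed: int = 1
    footprint_conditions: list = field(default_factory=list)  # [treated, reference]
    abc_min: float = 0.02
    cp_min: float = 15.0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if not cfg.base_dir or cfg.base_dir == ".":
            cfg.base_dir = str(path.parent)
        return cfg

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def validate(self) -> None:
        required = {
            "methylation": self.methylation,
            "peaks.tet1": self.peaks.get("tet1"),
            "peaks.tet2": self.peaks.get("tet2"),
        }
        for name, value in required.items():
            if not value:
                raise ConfigError(f"missing required config field: {name}")
        params = self.params()
        need = {("WT", 0), ("WT", params.timepoint), ("DKO", params.timepoint)}
        have = {(m["genotype"], m["timepoint"]) for m in self.methylation}
        missing = need - have
        if missing:
            raise ConfigError(
                "methylation missing required genotype/timepoint combinations: "
                + ", ".join(f"{g} {t}h" for g, t in sorted(missing))
            )
        paths = [m["path"] for m in self.methylation]
        paths += [p for p in self.peaks.values()]
        paths += [p for p in self.annotations.values()]
        paths += list(self.cut_tracks.values())
        for extra in (self.footprint_regions, self.fasta, self.contacts, self.truth):
            if extra:
                paths.append(extra)
        if self.counts:
            paths += list(self.counts.values())
        for p in paths:
            if not self.resolve(p).exists():
                raise ConfigError(f"input file does not exist: {p}")

    def params(self) -> TargetParams:
        return TargetParams(**self.target_params)


def config_from_sim_dir(sim_dir: str | Path, outdir: str | Path,
                        seed: int = 1) -> PipelineConfig:
    """Build a run config pointing at a simulate_dataset output directory."""
    sim_dir = Path(sim_dir)
    with open(sim_dir / "truth.json") as fh:
        truth = json.load(fh)
    files = truth["annotation_files"]
    meth = []
    for label, fname in files["methylation"].items():
        genotype, tp, rep = label.split("_")
        meth.append({
            "path": fname,
            "genotype": genotype,
            "timepoint": int(tp.rstrip("h")),
            "replicate": int(rep.lstrip("r")),
        })
    with open(sim_dir / "simconfig.json") as fh:
        sim_cfg = json.load(fh)
    conditions = sorted(files["cut_tracks"], key=lambda c: not c.startswith("WT"))
    return PipelineConfig(
        methylation=sorted(meth, key=lambda m: m["path"]),
        peaks={k: files[k] for k in
               ("tet1", "tet2", "tfe3", "p300", "h3k27ac", "h3k27me3", "h3k4me1")},
        annotations={"promoters": files["promoters"], "l1md": files["l1md"]},
        cut_tracks={c: files["cut_tracks"][c] for c in conditions},
        footprint_regions=files["footprint_regions"],
        fasta="genome.fa",
        motifs=[{"name": "planted_motif", "consensus": truth["motif_consensus"]}],
        counts={"matrix": "counts.tsv", "features": "features.tsv"},
        contacts="contacts.tsv",
        truth="truth.json",
        outdir=str(outdir),
        base_dir=str(sim_dir),
        target_params={"timepoint": sim_cfg["target_timepoint"]},
        # at most half the genome tiles can be controls; the study-size
        # genome (2 x 2 Mb, 1 kb tiles) keeps the full 2,000
        control_n=min(2000, sim_cfg["n_chrom"] * sim_cfg["chrom_length"] // 2000),
        control_seed=seed,
        footprint_seed=seed,
        footprint_conditions=conditions[:2],
        autosomes=[f"chr{i + 1}" for i in range(sim_cfg["n_chrom"])],
    )


def _stage(report: dict, name: str, **counts) -> None:
    report["stages"].append({"stage": name, **counts})


def _pooled_filtered(cfg: PipelineConfig, genotype: str, timepoint: int
                     ) -> MethylationProfile:
    entries = [m for m in cfg.methylation
               if m["genotype"] == genotype and m["timepoint"] == timepoint]
    profiles = [
        MethylationProfile.read_tsv(
            cfg.resolve(m["path"]),
            SampleLabel(m["genotype"], m["timepoint"], m.get("replicate", 1)),
        )
        for m in entries
    ]
    pooled = pool_profiles(profiles)
    return filter_cpgs(pooled, cfg.min_cov, cfg.max_cov, cfg.autosomes)


def _targets_intervalset(df: pd.DataFrame, mask=None) -> IntervalSet:
    sub = df if mask is None else df.loc[mask]
    return IntervalSet(
        [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()]
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the (JSON-serializable) run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)  # relative to the invoking directory
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.params()
    report: dict = {
        "tool": "tetdormancy",
        "version": __version__,
        "parameters": {
            "target_params": asdict(params),
            "min_cov": cfg.min_cov, "max_cov": cfg.max_cov,
            "tile_size": cfg.tile_size,
            "control_n": cfg.control_n, "control_seed": cfg.control_seed,
            "footprint_flank": cfg.footprint_flank,
            "footprint_n_shuffles": cfg.footprint_n_shuffles,
            "footprint_seed": cfg.footprint_seed,
            "abc_min": cfg.abc_min, "cp_min": cfg.cp_min,
        },
        "stages": [],
    }

    # --- methylation filtering -------------------------------------------------
    try:
        wt0 = _pooled_filtered(cfg, "WT", 0)
        wtt = _pooled_filtered(cfg, "WT", params.timepoint)
        dkot = _pooled_filtered(cfg, "DKO", params.timepoint)
    except Exception as exc:
        raise StageError(f"stage filter: {exc}") from exc
    _stage(report, "filter", n_cpgs_wt0=len(wt0), n_cpgs_wt_t=len(wtt),
           n_cpgs_dko_t=len(dkot))

    # --- candidates ------------------------------------------------------------
    try:
        tet1 = read_bed(cfg.resolve(cfg.peaks["tet1"]))
        tet2 = read_bed(cfg.resolve(cfg.peaks["tet2"]))
        cand = candidate_regions(tet1, tet2, params.min_overlap)
    except Exception as exc:
        raise StageError(f"stage candidates: {exc}") from exc
    cand_ivs = _targets_intervalset(cand)
    _stage(report, "candidates", n_candidates=len(cand),
           n_tet1_peaks=len(tet1), n_tet2_peaks=len(tet2))

    # --- target calling --------------------------------------------------------
    try:
        m0 = region_methylation(wt0, cand_ivs, params.min_cpgs)
        mt = region_methylation(wtt, cand_ivs, params.min_cpgs)
        md = region_methylation(dkot, cand_ivs, params.min_cpgs)
        called = call_targets(cand, m0, mt, md, params)
    except Exception as exc:
        raise StageError(f"stage call: {exc}") from exc
    _stage(report, "call", n_targets=int(called["is_target"].sum()),
           n_undetermined=int(called["undetermined"].sum()))

    # --- annotation ------------------------------------------------------------
    try:
        enh = EnhancerAnnotation(IntervalSet([]), IntervalSet([]))
        if all(k in cfg.peaks for k in ("p300", "h3k27ac", "h3k27me3", "h3k4me1")):
            enh = classify_enhancers(
                read_bed(cfg.resolve(cfg.peaks["p300"])),
                read_bed(cfg.resolve(cfg.peaks["h3k27ac"])),
                read_bed(cfg.resolve(cfg.peaks["h3k27me3"])),
                read_bed(cfg.resolve(cfg.peaks["h3k4me1"])),
            )
        promoters = (read_bed(cfg.resolve(cfg.annotations["promoters"]))
                     if "promoters" in cfg.annotations else IntervalSet([]))
        l1md = (read_bed(cfg.resolve(cfg.annotations["l1md"]))
                if "l1md" in cfg.annotations else IntervalSet([]))
        annotated = annotate_targets(called, promoters, enh, l1md)
    except Exception as exc:
        raise StageError(f"stage annotate: {exc}") from exc
    summary = target_summary(annotated)
    report["target_summary"] = summary
    _stage(report, "annotate", n_active_enhancers=len(enh.active),
           n_primed_enhancers=len(enh.primed))
    annotated.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    _targets_intervalset(annotated, annotated["is_target"]).write_bed(
        outdir / "targets.bed")

    # --- canonical TFE3 targets ------------------------------------------------
    if "tfe3" in cfg.peaks:
        tfe3 = read_bed(cfg.resolve(cfg.peaks["tfe3"]))
        canonical = canonical_tfe3_targets(tfe3, annotated)
        canonical.write_bed(outdir / "canonical_tfe3.bed")
        _stage(report, "canonical_tfe3", n_tfe3_peaks=len(tfe3),
               n_canonical=len(canonical))

    # --- control regions -------------------------------------------------------
    try:
        tiles0 = tile_methylation(wt0, cfg.tile_size, params.min_cpgs)
        tilest = tile_methylation(wtt, cfg.tile_size, params.min_cpgs)
        common = tiles0.merge(tilest, on=["chrom", "start", "end"],
                              suffixes=("_0", "_t"))
        deltas = common[["chrom", "start", "end"]].copy()
        deltas["delta"] = common["rate_t"] - common["rate_0"]
        deltas = deltas.dropna(subset=["delta"]).reset_index(drop=True)
        controls = sample_control_regions(deltas, cfg.control_n, cfg.control_seed)
    except Exception as exc:
        raise StageError(f"stage controls: {exc}") from exc
    controls.write_bed(outdir / "controls.bed")
    _stage(report, "controls", n_tiles=len(deltas), n_controls=len(controls))

    # --- footprints ------------------------------------------------------------
    fp_rows = []
    if cfg.fasta and cfg.cut_tracks and cfg.footprint_regions:
        try:
            seqs = load_fasta(cfg.resolve(cfg.fasta))
            fp_regions = read_bed(cfg.resolve(cfg.footprint_regions))
            tracks = {c: CutTrack.from_bedgraph(cfg.resolve(p), name=c)
                      for c, p in cfg.cut_tracks.items()}
            conds = cfg.footprint_conditions or sorted(tracks)
            occ_by_motif = {}
            for spec_ in cfg.motifs:
                pwm = PositionWeightMatrix.from_consensus(
                    spec_["name"], spec_["consensus"])
                occ = scan_motifs(seqs, pwm, fp_regions)
                occ_by_motif[spec_["name"]] = occ
                for c in conds:
                    res = footprint_score(tracks[c], occ, cfg.footprint_flank,
                                          motif=spec_["name"], condition=c)
                    fp_rows.append({"motif": spec_["name"], "condition": c,
                                    "score": res.score, "z": "",
                                    "n_occurrences": res.n_occurrences})
                if len(conds) >= 2:
                    diff = differential_footprint(
                        tracks[conds[0]], tracks[conds[1]], occ, fp_regions,
                        cfg.footprint_n_shuffles, cfg.footprint_seed,
                        cfg.footprint_flank, motif=spec_["name"])
                    fp_rows.append({
                        "motif": spec_["name"],
                        "condition": f"{conds[0]}-vs-{conds[1]}",
                        "score": diff["delta"], "z": diff["z"],
                        "n_occurrences": diff["n_occurrences"],
                    })
        except Exception as exc:
            raise StageError(f"stage footprint: {exc}") from exc
        fp_df = pd.DataFrame(fp_rows)
        fp_df.to_csv(outdir / "footprints.tsv", sep="\t", index=False)
        report["footprints"] = fp_rows
        _stage(report, "footprint", n_motifs=len(cfg.motifs),
               n_conditions=len(cfg.cut_tracks))

        # --- motif enrichment (targets vs non-target candidates) ---------------
        try:
            tgt_ivs = _targets_intervalset(annotated, annotated["is_target"])
            bg_ivs = _targets_intervalset(annotated, ~annotated["is_target"])
            # enrichment needs occurrences genome-wide over both sets; rescan
            universe = IntervalSet(list(tgt_ivs) + list(bg_ivs))
            occ_sets = {}
            for spec_ in cfg.motifs:
                pwm = PositionWeightMatrix.from_consensus(
                    spec_["name"], spec_["consensus"])
                occ = scan_motifs(seqs, pwm, universe)
                occ_sets[spec_["name"]] = occurrences_to_intervalset(
                    occ, name=spec_["name"])
            enrich = motif_enrichment(tgt_ivs, bg_ivs, occ_sets)
        except Exception as exc:
            raise StageError(f"stage enrich: {exc}") from exc
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = enrich.to_dict(orient="records")
        _stage(report, "enrich", n_motifs=len(enrich))

    # --- spike-in normalization ------------------------------------------------
    norm = None
    if cfg.counts:
        try:
            cm = CountMatrix.read_tsv(cfg.resolve(cfg.counts["matrix"]),
                                      cfg.resolve(cfg.counts["features"]))
            factors = spikein_size_factors(cm)
            norm = normalize_counts(cm, length_normalize=True)
            fam = repeat_family_expression(cm)
        except Exception as exc:
            raise StageError(f"stage normalize: {exc}") from exc
        norm.to_csv(outdir / "normalized_tpm.tsv", sep="\t")
        fam.to_csv(outdir / "repeat_families.tsv", sep="\t")
        endog = norm.loc[~cm.spike_mask]
        report["expression"] = {
            "size_factors": {k: round(float(v), 6) for k, v in factors.items()},
            "global_mean_normalized_tpm": {
                k: round(float(v), 6) for k, v in endog.mean(axis=0).items()
            },
        }
        _stage(report, "normalize", n_features=len(cm.features),
               n_spikeins=int(cm.spike_mask.sum()), n_samples=len(cm.samples))

    # --- contact-gene assignment -------------------------------------------------
    if cfg.contacts:
        try:
            contacts = read_contacts(cfg.resolve(cfg.contacts))
            tgt = annotated.loc[annotated["is_target"]
                                & annotated["feature"].isin(
                                    ["active_enhancer", "L1Md"])]
            elements = _targets_intervalset(tgt)
            classes = [
                "enhancer" if f == "active_enhancer" else "L1Md"
                for f in tgt.sort_values(["chrom", "start", "end"])["feature"]
            ]
            assignments = assign_contact_genes(elements, classes, contacts,
                                               cfg.abc_min, cfg.cp_min)
        except Exception as exc:
            raise StageError(f"stage contacts: {exc}") from exc
        assignments.to_csv(outdir / "contacts_assigned.tsv", sep="\t", index=False)
        n_assigned = len(assignments)
        _stage(report, "contacts", n_elements=len(elements),
               n_assignments=n_assigned)
        if norm is not None and n_assigned:
            expr = summarize_contact_gene_expression(assignments, norm)
            report["contact_gene_expression"] = {
                k: {c: round(float(x), 6) for c, x in row.items()}
                for k, row in expr.T.to_dict().items()
            }

    # --- truth scoring (synthetic runs only) -------------------------------------
    if cfg.truth:
        from .simulate import SimTruth

        truth = SimTruth.from_json(cfg.resolve(cfg.truth))
        truth_keys = {
            (r.chrom, int(r.start), int(r.end))
            for r in truth.candidates.loc[truth.candidates["is_target"]].itertuples()
        }
        called_keys = {
            (r.chrom, int(r.start), int(r.end))
            for r in annotated.loc[annotated["is_target"]].itertuples()
        }
        tp = len(truth_keys & called_keys)
        precision = tp / len(called_keys) if called_keys else 0.0
        recall = tp / len(truth_keys) if truth_keys else 0.0
        report["truth_recovery"] = {
            "n_true_targets": len(truth_keys),
            "n_called_targets": len(called_keys),
            "true_positives": tp,
            "precision": round(precision, 6),
            "recall": round(recall, 6),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
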