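"""Spike-in normalization, repeat and pathway expression, contact-based gene assignment.

Dormancy entry represses the transcriptome globally.  Per-sample
normalizations (plain TPM, library-size CPM) are blind to such global
shifts because they force every sample to the same total; exogenous ERCC
spike-in RNAs, added in proportion to cell number, provide the anchor
that makes global repression visible.  Size factors are estimated by
DESeq-style median-of-ratios restricted to spike-in rows, and applied
after the length/TPM transform so that gene values scale with true
per-cell output.

Also here: aggregation of repeat-consensus counts into per-family
expression, pathway mean-TPM summaries, and assignment of genes to
regulatory elements through activity-by-contact (ABC) scores for
enhancers and Hi-C contact probabilities for L1Md repeat promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "CountMatrix",
    "spikein_size_factors",
    "normalize_counts",
    "repeat_family_expression",
    "pathway_expression",
    "assign_contact_genes",
    "summarize_contact_gene_expression",
    "read_contacts",
]

_FEATURE_COLS = ["id", "length", "spike_in", "repeat_family", "repeat_class"]


class CountMatrix:
    """Feature x sample integer counts with a feature-annotation sidecar.

    ``features`` columns: id, length (bp), spike_in (bool), repeat_family
    (str or empty), repeat_class (str or empty, e.g. LINE/LTR).  ``counts``
    is indexed by feature id with sample columns.
    """

    def __init__(self, features: pd.DataFrame, counts: pd.DataFrame):
        features = features.copy()
        for col, default in (("repeat_family", ""), ("repeat_class", "")):
            if col not in features.columns:
                features[col] = default
        missing = [c for c in _FEATURE_COLS if c not in features.columns]
        if missing:
            raise ValueError(f"features missing columns: {missing}")
        features = features.set_index("id", drop=False) if features.index.name != "id" else features
        if not features.index.equals(counts.index):
            counts = counts.loc[features["id"].to_numpy()]
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if int(features["spike_in"].sum()) < 2:
            raise ValueError("need at least 2 spike-in features")
        self.features = features
        self.counts = counts

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def spike_mask(self) -> np.ndarray:
        return self.features["spike_in"].to_numpy(bool)

    # -- I/O: counts TSV + feature sidecar TSV -----------------------------------
    @classmethod
    def read_tsv(cls, counts_path: str | Path, features_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        feats = pd.read_csv(
            features_path, sep="\t",
            dtype={"id": str, "length": np.int64, "repeat_family": str, "repeat_class": str},
            keep_default_na=False,
        )
        feats["spike_in"] = feats["spike_in"].astype(str).str.lower().isin({"true", "1"})
        return cls(feats, counts)

    def write_tsv(self, counts_path: str | Path, features_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.features[_FEATURE_COLS].to_csv(features_path, sep="\t", index=False)


def _median_of_ratios(values: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors from a (features x samples) value matrix."""
    arr = values.to_numpy(float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no feature has nonzero values in every sample")
    sub = arr[usable]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def spikein_size_factors(m: CountMatrix, values: pd.DataFrame | None = None) -> pd.Series:
    """Per-sample size factors from spike-in rows (median-of-ratios).

    factor_s = median over spike-in rows of value(row, s) / geometric mean
    of that row across samples.  Dividing a matrix by these factors
    equalizes the spike-ins across samples, so any residual global shift
    in the endogenous features reflects true per-cell changes.

    ``values`` optionally supplies a transformed matrix (e.g. TPM) on
    which to measure the ratios; by default raw counts are used.
    """
    mat = m.counts if values is None else values
    spikes = mat.loc[m.spike_mask]
    if (spikes.sum(axis=0) == 0).any():
        bad = spikes.columns[(spikes.sum(axis=0) == 0)].tolist()
        raise ValueError(f"samples with all-zero spike-ins: {bad}")
    return _median_of_ratios(spikes)


def _tpm(m: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million with the per-sample sum over non-spike-ins.

    Reads-per-kilobase are rescaled so that the *endogenous* (non-spike)
    values sum to 1e6 in every sample; spike-in rows are carried through
    on the same scale so spike-based factors can be measured on them.
    """
    rpk = m.counts.div(m.features["length"].to_numpy() / 1000.0, axis=0)
    denom = rpk.loc[~m.spike_mask].sum(axis=0)
    return rpk.div(denom, axis=1) * 1e6


def normalize_counts(
    m: CountMatrix,
    factors: pd.Series | None = None,
    length_normalize: bool = False,
) -> pd.DataFrame:
    """Spike-in-normalized expression values.

    With ``length_normalize=False``: value = count / factor (factors
    default to spike-in median-of-ratios on raw counts).

    With ``length_normalize=True``: counts are first transformed to TPM
    (non-spike-in rows summing to 1e6 per sample), then the whole matrix
    is divided by spike-in factors measured on the TPM-scale spike-in
    rows.  On this scale, a globally repressed sample shows a
    proportionally lower mean — exactly the signal plain TPM hides.
    """
    if length_normalize:
        tpm = _tpm(m)
        if factors is None:
            factors = spikein_size_factors(m, values=tpm)
        return tpm.div(factors, axis=1)
    if factors is None:
        factors = spikein_size_factors(m)
    if (factors <= 0).any():
        raise ValueError("size factors must be > 0")
    return m.counts.div(factors, axis=1)


def repeat_family_expression(m: CountMatrix) -> pd.DataFrame:
    """Family x sample expression from repeat-consensus counts.

    Per member: spike-in-normalized count divided by consensus length in
    kb; per family: sum over members.  The output is ordered by repeat
    class (e.g. LINE before LTR) then family name.
    """
    rep = m.features["repeat_family"] != ""
    if not rep.any():
        raise ValueError("no features carry a repeat_family annotation")
    factors = spikein_size_factors(m)
    norm = m.counts.div(factors, axis=1).div(m.features["length"].to_numpy() / 1000.0, axis=0)
    sub = norm.loc[rep.to_numpy()].copy()
    meta = m.features.loc[rep.to_numpy(), ["repeat_family", "repeat_class"]]
    out = sub.groupby(meta["repeat_family"]).sum()
    class_of = meta.drop_duplicates("repeat_family").set_index("repeat_family")["repeat_class"]
    out["repeat_class"] = class_of.reindex(out.index)
    out = out.sort_values(["repeat_class", "repeat_family"], kind="mergesort",
                          key=lambda s: s if s.name != "repeat_family" else s.str.lower())
    return out.set_index("repeat_class", append=True).swaplevel()


def pathway_expression(
    tpm: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    min_genes: int = 10,
) -> pd.DataFrame:
    """Pathway x sample mean TPM over member genes.

    Duplicate gene ids within a set count once; genes absent from the
    matrix are ignored; pathways with fewer than ``min_genes`` genes
    present are dropped.
    """
    rows = {}
    for name in sorted(gene_sets):
        genes = sorted(set(gene_sets[name]) & set(tpm.index))
        if len(genes) >= min_genes:
            rows[name] = tpm.loc[genes].mean(axis=0)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=tpm.columns)


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Element-gene contact table: chrom, start, end, gene_id, abc_score, contact_probability."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
    )
    need = {"chrom", "start", "end", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"contacts table must have columns {sorted(need)}")
    return df


def assign_contact_genes(
    elements: IntervalSet,
    element_classes: Sequence[str],
    contacts: pd.DataFrame,
    abc_min: float = 0.02,
    cp_min: float = 15.0,
) -> pd.DataFrame:
    """Assign genes to elements through published contact predictions.

    Enhancer-class elements keep genes whose overlapping contact record
    has ``abc_score >= abc_min`` (inclusive at the recommended cutoff);
    L1Md-class elements keep genes with ``contact_probability > cp_min``
    (strict).  Elements match contact records by >= 1 bp overlap.
    ``element_classes`` holds "enhancer" or "L1Md" per element, aligned
    with ``elements``.

    Returns a tidy frame: element chrom/start/end, element_class, gene_id.
    """
    if len(element_classes) != len(elements):
        raise ValueError("element_classes must align with elements")
    bad = set(element_classes) - {"enhancer", "L1Md"}
    if bad:
        raise ValueError(f"unknown element classes: {sorted(bad)}")
    records = []
    contact_ivs = IntervalSet(
        [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in contacts.itertuples()],
    )
    # map each contact interval to its source rows (duplicates collapse)
    rows_of: dict[GenomicInterval, list[int]] = {}
    for idx, r in enumerate(contacts.itertuples()):
        rows_of.setdefault(GenomicInterval(r.chrom, int(r.start), int(r.end)), []).append(idx)
    for elem, klass in zip(elements, element_classes):
        one = IntervalSet([elem])
        hits = contact_ivs.intersect_fraction(one, 1) if len(contact_ivs) else np.zeros(0, bool)
        for civ, hit in zip(contact_ivs, hits):
            if not hit:
                continue
            for idx in rows_of[civ]:
                row = contacts.iloc[idx]
                if klass == "enhancer":
                    score = row.get("abc_score", np.nan)
                    if pd.notna(score) and score >= abc_min:
                        records.append((elem.chrom, elem.start, elem.end, klass, row["gene_id"]))
                else:
                    cp = row.get("contact_probability", np.nan)
                    if pd.notna(cp) and cp > cp_min:
                        records.append((elem.chrom, elem.start, elem.end, klass, row["gene_id"]))
    out = pd.DataFrame(
        records, columns=["chrom", "start", "end", "element_class", "gene_id"]
    ).drop_duplicates().reset_index(drop=True)
    return out


def summarize_contact_gene_expression(
    assignments: pd.DataFrame,
    tpm: pd.DataFrame,
) -> pd.DataFrame:
    """Median and quartiles of assigned-gene expression per sample.

    Genes are deduplicated across assignments; an error is raised when no
    assigned gene is present in the expression matrix.
    """
    if assignments.empty:
        raise ValueError("assignments are empty")
    genes = sorted(set(assignments["gene_id"]) & set(tpm.index))
    if not genes:
        raise ValueError("no assigned gene present in the expression matrix")
    sub = tpm.loc[genes]
    return pd.DataFrame(
        {
            "median": sub.median(axis=0),
            "q1": sub.quantile(0.25, axis=0),
            "q3": sub.quantile(0.75, axis=0),
            "n_genes": len(genes),
        }
    )
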