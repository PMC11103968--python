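"""Variant filter cascades and variant-category classifiers.

Without matched normal tissue, the call set mixes somatic and germline
variants.  The small-variant cascade keeps PASS calls, discards common
germline variants by population allele frequency (gnomAD MAF > 0.05%), and
discards low-VAF calls (VAF < 0.1) that are enriched for shearing artifacts.
A stricter refinement (VAF >= 0.15, >= 20 supporting reads, coding/UTR
consequences) precedes mutational-recurrence analysis.  Structural variants
require PASS, >= 3 supporting read pairs, no exact-breakpoint population
match, and must not recur across >= 4 myeloid AND >= 4 lymphatic entities.

Boundary rulings (the thresholds are stated as discard conditions and read
literally): keep at MAF exactly 0.05%, keep at VAF exactly 0.1 / 0.15;
promoter window is strict (< 2000 bp); splice-affecting score cutoff is
inclusive (>= 0.2).  Missing gnomAD AF means the variant is absent from the
population database and is treated as frequency 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Config, DEFAULT_CONFIG

logger = logging.getLogger("txcensus")

LINEAGES = ("myeloid", "lymphatic")


def _validate_vaf(variants: pd.DataFrame) -> None:
    vaf = variants["vaf"]
    if ((vaf < 0) | (vaf > 1)).any():
        bad = variants.loc[(vaf < 0) | (vaf > 1)]
        raise ValueError(
            f"VAF outside [0, 1] for {len(bad)} variants, e.g. "
            f"{bad.iloc[0]['sample_id']}/{bad.iloc[0]['gene_id']}")


def filter_small_variants(variants: pd.DataFrame,
                          config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """PASS quality, gnomAD MAF <= 0.05%, VAF >= 0.1.

    Per-branch rejection counts are logged.  Missing gnomad_af is treated
    as 0.
    """
    _validate_vaf(variants)
    af = variants["gnomad_af"].fillna(0.0)
    is_pass = variants["filter_status"] == "PASS"
    af_ok = af <= config.max_gnomad_af
    vaf_ok = variants["vaf"] >= config.min_vaf
    keep = is_pass & af_ok & vaf_ok
    logger.info("small-variant filter: %d in, %d kept (rejected: %d non-PASS, "
                "%d common, %d low-VAF)", len(variants), int(keep.sum()),
                int((~is_pass).sum()), int((is_pass & ~af_ok).sum()),
                int((is_pass & af_ok & ~vaf_ok).sum()))
    return variants[keep].reset_index(drop=True)


def _parse_entity_occurrence(value) -> dict[str, dict[str, int]]:
    """Parse the per-lineage entity occurrence field.

    Serialized as ``lineage:entity=count`` items joined by ``;`` (e.g.
    ``myeloid:AML=3;lymphatic:MZL=1``); a dict of dicts passes through.
    """
    if isinstance(value, dict):
        out = value
    elif value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        out = {}
    else:
        out = {}
        for item in str(value).split(";"):
            if not item:
                continue
            key, count = item.rsplit("=", 1)
            lineage, entity = key.split(":", 1)
            out.setdefault(lineage, {})[entity] = int(count)
    for lineage in out:
        if lineage not in LINEAGES:
            raise ValueError(f"unknown lineage tag: {lineage!r}")
    return out


def filter_structural_variants(svs: pd.DataFrame,
                               config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """PASS, >= 3 paired reads, no exact population-SV breakpoint match, and
    not recurrent in >= 4 myeloid AND >= 4 lymphatic entities."""
    occ = svs["entity_occurrence"].map(_parse_entity_occurrence)
    n_myeloid = occ.map(lambda d: sum(1 for c in d.get("myeloid", {}).values() if c > 0))
    n_lymph = occ.map(lambda d: sum(1 for c in d.get("lymphatic", {}).values() if c > 0))
    is_pass = svs["filter_status"] == "PASS"
    support_ok = svs["paired_read_support"] >= config.sv_min_paired_reads
    not_known = ~svs["gnomad_sv_exact_match"].astype(bool)
    k = config.sv_max_recurrent_entities
    not_recurrent = ~((n_myeloid >= k) & (n_lymph >= k))
    keep = is_pass & support_ok & not_known & not_recurrent
    logger.info("SV filter: %d in, %d kept", len(svs), int(keep.sum()))
    return svs[keep].reset_index(drop=True)


def filter_for_recurrence_analysis(variants: pd.DataFrame,
                                   config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Stricter refinement before mutational-recurrence tools: VAF >= 0.15,
    >= 20 supporting reads, and coding/UTR consequences only (impact HIGH/
    MODERATE/LOW or a UTR / coding-sequence consequence term)."""
    _validate_vaf(variants)
    vaf_ok = variants["vaf"] >= config.recurrence_min_vaf
    reads_ok = variants["read_support"] >= config.recurrence_min_reads
    impact_ok = variants["impact"].isin(config.coding_impacts)
    cons_ok = variants["consequences"].map(
        lambda c: bool(_as_tags(c) & set(config.coding_utr_consequences)))
    keep = vaf_ok & reads_ok & (impact_ok | cons_ok)
    logger.info("recurrence filter: %d in, %d kept", len(variants), int(keep.sum()))
    return variants[keep].reset_index(drop=True)


def _as_tags(consequences) -> set[str]:
    if isinstance(consequences, (set, frozenset, list, tuple)):
        return set(consequences)
    if consequences is None or (isinstance(consequences, float) and np.isnan(consequences)):
        return set()
    return {t for t in str(consequences).split(",") if t}


def classify_promoter_variant(position, tss) -> bool | np.ndarray:
    """Promoter variant: strictly less than 2000 bp from the TSS,
    strand-agnostic."""
    tss = np.asarray(tss, dtype=float)
    if np.isnan(tss).any():
        raise ValueError("gene has no annotated TSS")
    out = np.abs(np.asarray(position, dtype=float) - tss) < 2000
    return out if out.ndim else bool(out)


def classify_vep_splice_related(consequences,
                                config: Config = DEFAULT_CONFIG) -> bool:
    """True iff any consequence term is splice_acceptor_variant,
    splice_donor_variant, or splice_region_variant."""
    return bool(_as_tags(consequences) & set(config.vep_splice_terms))


def classify_splice_affecting(predictions: pd.DataFrame,
                              config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Classify splice-variant predictions at score >= 0.2 (inclusive).

    Returns one aberration call per (gene, sample) with any qualifying
    variant; p-value fields are NA (the score is a prediction, not a test),
    effect is the best score, and the qualifying variant IDs are retained as
    evidence.
    """
    score = predictions["score"]
    if ((score < 0) | (score > 1)).any():
        raise ValueError("splice prediction scores must lie in [0, 1]")
    hits = predictions[score >= config.splice_affecting_min_score]
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "sample_id", "category",
                                     "p_value", "adjusted_p", "effect", "variants"])
    grouped = (hits.sort_values(["gene_id", "sample_id", "variant_id"])
               .groupby(["gene_id", "sample_id"], as_index=False)
               .agg(effect=("score", "max"),
                    variants=("variant_id", lambda v: ",".join(v))))
    grouped["category"] = "splice_variant"
    grouped["p_value"] = np.nan
    grouped["adjusted_p"] = np.nan
    return grouped[["gene_id", "sample_id", "category", "p_value",
                    "adjusted_p", "effect", "variants"]]


def classify_cnv_overlap(gene: pd.Series, segments: pd.DataFrame) -> set[str]:
    """Copy-number status of a gene against called copy-ratio segments.

    Any overlap (>= 1 bp, half-open intervals) with a "+" segment flags
    gain, with a "-" segment flags loss; both can be reported; otherwise
    {neutral}.
    """
    same_chrom = segments[segments["chrom"] == gene["chrom"]]
    overlap = same_chrom[(same_chrom["start"] < gene["end"]) &
                         (same_chrom["end"] > gene["start"])]
    flags = set()
    if (overlap["call"] == "+").any():
        flags.add("gain")
    if (overlap["call"] == "-").any():
        flags.add("loss")
    return flags or {"neutral"}
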