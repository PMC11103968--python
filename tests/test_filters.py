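"""Variant filter cascades: boundary rulings, idempotence, monotonicity, and
exact agreement with the generator's planted truth."""

import numpy as np
import pandas as pd
import pytest

from txcensus.filters import (filter_small_variants, filter_structural_variants,
                              filter_for_recurrence_analysis,
                              classify_promoter_variant,
                              classify_vep_splice_related,
                              classify_splice_affecting, classify_cnv_overlap)
from txcensus.simulate import SimulationConfig, simulate_variants


def _small(filter_status="PASS", gnomad_af=0.0001, vaf=0.5, read_support=30,
           consequences="missense_variant", impact="MODERATE"):
    return dict(sample_id="s1", gene_id="g1", position=100,
                filter_status=filter_status, gnomad_af=gnomad_af, vaf=vaf,
                read_support=read_support, consequences=consequences,
                impact=impact)


@pytest.mark.parametrize("variant,kept", [
    (_small(gnomad_af=0.0004, vaf=0.5), True),        # all criteria satisfied
    (_small(gnomad_af=0.0006), False),                # common germline
    (_small(gnomad_af=0.0005), True),                 # boundary: kept at exactly 0.05%
    (_small(vaf=0.09), False),                        # low-VAF artifact
    (_small(vaf=0.10), True),                         # boundary: kept at exactly 0.1
    (_small(filter_status="LowQual"), False),         # PASS requirement
    (_small(gnomad_af=np.nan), True),                 # absent from gnomAD = maximally rare
])
def test_small_variant_filter_branches(variant, kept):
    out = filter_small_variants(pd.DataFrame([variant]))
    assert len(out) == (1 if kept else 0)


def test_small_variant_filter_rejects_bad_vaf():
    with pytest.raises(ValueError, match="VAF"):
        filter_small_variants(pd.DataFrame([_small(vaf=1.5)]))


def _sv(filter_status="PASS", support=5, known=False, occ=""):
    return dict(sample_id="s1", gene_id="g1", filter_status=filter_status,
                paired_read_support=support, gnomad_sv_exact_match=known,
                entity_occurrence=occ)


def _occ(n_my, n_ly):
    my = ";".join(f"myeloid:M{i}=1" for i in range(n_my))
    ly = ";".join(f"lymphatic:L{i}=1" for i in range(n_ly))
    return ";".join(x for x in (my, ly) if x)


@pytest.mark.parametrize("sv,kept", [
    (_sv(support=2), False),                          # needs >= 3 read pairs
    (_sv(support=3), True),
    (_sv(known=True), False),                         # exact population match
    (_sv(occ=_occ(4, 4)), False),                     # recurrent in both lineages
    (_sv(occ=_occ(4, 3)), True),                      # conjunction needs both >= 4
    (_sv(occ=_occ(3, 4)), True),
    (_sv(filter_status="LowQual"), False),
])
def test_sv_filter_branches(sv, kept):
    out = filter_structural_variants(pd.DataFrame([sv]))
    assert len(out) == (1 if kept else 0)


def test_sv_filter_rejects_unknown_lineage():
    with pytest.raises(ValueError, match="lineage"):
        filter_structural_variants(pd.DataFrame([_sv(occ="plasma:X=1")]))


@pytest.mark.parametrize("variant,kept", [
    (_small(vaf=0.12), False),                        # VAF < 0.15
    (_small(vaf=0.15), True),                         # boundary inclusive
    (_small(read_support=19), False),                 # < 20 reads
    (_small(impact="MODIFIER", consequences="intergenic_variant"), False),
    (_small(impact="MODIFIER", consequences="5_prime_UTR_variant"), True),
])
def test_recurrence_filter_branches(variant, kept):
    out = filter_for_recurrence_analysis(pd.DataFrame([variant]))
    assert len(out) == (1 if kept else 0)


def test_filters_idempotent_and_nested():
    cfg = SimulationConfig(seed=11, n_genes=100)
    small, sv, _, _ = simulate_variants(cfg)
    once = filter_small_variants(small)
    twice = filter_small_variants(once)
    pd.testing.assert_frame_equal(once, twice)
    rec = filter_for_recurrence_analysis(once)
    assert set(rec["variant_id"]) <= set(once["variant_id"])
    sv_once = filter_structural_variants(sv)
    pd.testing.assert_frame_equal(sv_once, filter_structural_variants(sv_once))


def test_filters_match_planted_truth_exactly():
    cfg = SimulationConfig(seed=5, n_genes=100, n_variants_per_branch=3)
    small, sv, _, truth = simulate_variants(cfg)
    kept = filter_small_variants(small)
    expected = set(truth.small_variant_truth.loc[
        truth.small_variant_truth["survives_filter"], "variant_id"])
    assert set(kept["variant_id"]) == expected
    rec = filter_for_recurrence_analysis(kept)
    expected2 = set(truth.small_variant_truth.loc[
        truth.small_variant_truth["survives_recurrence_filter"], "variant_id"])
    assert set(rec["variant_id"]) == expected2
    kept_sv = filter_structural_variants(sv)
    expected_sv = set(truth.sv_truth.loc[truth.sv_truth["survives_filter"],
                                         "variant_id"])
    assert set(kept_sv["variant_id"]) == expected_sv


@pytest.mark.parametrize("distance,is_promoter", [(0, True), (1999, True),
                                                  (2000, False), (5000, False)])
def test_promoter_window_is_strict(distance, is_promoter):
    assert classify_promoter_variant(10_000 + distance, 10_000) is is_promoter
    assert classify_promoter_variant(10_000 - distance, 10_000) is is_promoter


def test_promoter_requires_tss():
    with pytest.raises(ValueError, match="TSS"):
        classify_promoter_variant(100, np.nan)


@pytest.mark.parametrize("consequences,expected", [
    ("splice_donor_variant", True),
    ("missense_variant", False),
    ("missense_variant,splice_region_variant", True),
    ({"splice_acceptor_variant"}, True),
])
def test_vep_splice_related(consequences, expected):
    assert classify_vep_splice_related(consequences) is expected


def test_splice_affecting_threshold_inclusive():
    pred = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g3"],
        "sample_id": ["s1", "s1", "s1", "s2"],
        "variant_id": ["v1", "v2", "v3", "v4"],
        "score": [0.36, 0.19, 0.2, 0.1]})
    calls = classify_splice_affecting(pred)
    pairs = set(zip(calls["gene_id"], calls["sample_id"]))
    assert pairs == {("g1", "s1"), ("g2", "s1")}
    g1 = calls[calls["gene_id"] == "g1"].iloc[0]
    assert g1["effect"] == 0.36 and g1["variants"] == "v1"


def test_splice_affecting_rejects_out_of_range_scores():
    bad = pd.DataFrame({"gene_id": ["g"], "sample_id": ["s"],
                        "variant_id": ["v"], "score": [1.2]})
    with pytest.raises(ValueError):
        classify_splice_affecting(bad)


def test_cnv_overlap_rules():
    gene = pd.Series({"chrom": "chr1", "start": 1000, "end": 2000})
    segs = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [0, 1999, 0], "end": [500, 3000, 5000],
        "call": ["-", "+", "-"], "log_copy_ratio": [-0.6, 0.5, -0.6]})
    # 1-bp overlap with the "+" segment counts; chr2 never overlaps
    assert classify_cnv_overlap(gene, segs) == {"gain"}
    assert classify_cnv_overlap(gene, segs.iloc[[2]]) == {"neutral"}
    both = segs.copy()
    both.loc[0, "end"] = 1500
    assert classify_cnv_overlap(gene, both) == {"gain", "loss"}
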