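"""Enrichment machinery: top-k restriction, recurrence strata, Fisher tests
against an exhaustive hypergeometric oracle, and variance components."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txcensus.enrichment import (fisher_enrichment, restrict_top_k_per_sample,
                                 stratify_genes_by_recurrence, driver_enrichment,
                                 variant_category_enrichment, overlap_summary,
                                 variance_components, significance_stars)

from conftest import hypergeom_pvalue


def _calls(rows):
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "category",
                                       "p_value", "adjusted_p", "effect"])


def test_top_k_keeps_most_significant():
    ps = [1e-9, 1e-7, 1e-5, 1e-3, 0.04]
    calls = _calls([(f"g{i}", "s1", "activation", p, p, 1.0)
                    for i, p in enumerate(ps)])
    out = restrict_top_k_per_sample(calls, k=3)
    assert sorted(out["gene_id"]) == ["g0", "g1", "g2"]


def test_top_k_fewer_than_k_and_tiebreak():
    calls = _calls([("g2", "s1", "activation", 0.01, 0.02, 1.0),
                    ("g1", "s1", "activation", 0.01, 0.02, 1.0)])
    out = restrict_top_k_per_sample(calls, k=1)
    assert out["gene_id"].tolist() == ["g1"]  # lexicographic tie-break
    both = restrict_top_k_per_sample(calls, k=3)
    assert len(both) == 2


def test_top_k_is_per_category():
    calls = _calls([("g1", "s1", "activation", 0.01, 0.02, 1.0),
                    ("g1", "s1", "underexpression", 0.01, 0.02, -2.0),
                    ("g2", "s1", "underexpression", 0.001, 0.01, -3.0)])
    out = restrict_top_k_per_sample(calls, k=1)
    assert len(out) == 2  # one per category


def test_recurrence_strata():
    rows = []
    for i in range(6):
        rows.append(("recur", f"s{i}", "activation", 1e-6, 1e-4, 1.0))
    rows.append(("single", "s0", "activation", 1e-6, 1e-4, 1.0))
    # called twice in the same sample in two categories: once per category
    rows.append(("dup", "s0", "activation", 1e-6, 1e-4, 1.0))
    rows.append(("dup", "s0", "splicing_over", 1e-6, 1e-4, 0.3))
    strata = stratify_genes_by_recurrence(_calls(rows))
    lookup = strata.set_index(["gene_id", "category"])["stratum"]
    assert lookup[("recur", "activation")] == ">5"
    assert lookup[("single", "activation")] == "1"
    assert lookup[("dup", "activation")] == "1"
    assert lookup[("dup", "splicing_over")] == "1"


@settings(deadline=None, max_examples=60, derandomize=True)
@given(a=st.integers(0, 15), b=st.integers(0, 15),
       c=st.integers(0, 15), d=st.integers(0, 15),
       alternative=st.sampled_from(["two-sided", "greater"]))
def test_fisher_matches_hypergeometric_oracle(a, b, c, d, alternative):
    res = fisher_enrichment(a, b, c, d, alternative=alternative)
    if res.testable:
        expected = hypergeom_pvalue(a, b, c, d, alternative)
        assert res.p_value == pytest.approx(expected, abs=1e-12)


def test_driver_enrichment_example():
    """Stratum of 10 genes with 4 drivers in a 100-gene universe with 10
    drivers: sample OR = (4*84)/(6*6) = 9.33; p from the hypergeometric."""
    genes = [f"g{i:03d}" for i in range(100)]
    drivers = genes[:10]
    ann = pd.DataFrame({
        "gene_id": genes,
        "is_driver_truth": [g in drivers for g in genes],
        "roles": ["TSG" if g in drivers else "" for g in genes],
        "tissue_types": "L"}).set_index("gene_id", drop=False)
    stratum_genes = drivers[:4] + genes[10:16]  # 4 drivers + 6 non-drivers
    strata = pd.DataFrame({"gene_id": stratum_genes, "category": "activation",
                           "n_samples": 1, "stratum": "1"})
    (res,) = driver_enrichment(strata, ann, "TSG", set(genes))
    assert (res.a, res.b, res.c, res.d) == (4, 6, 6, 84)
    assert res.odds_ratio == pytest.approx(4 * 84 / (6 * 6))
    assert res.p_value == pytest.approx(hypergeom_pvalue(4, 6, 6, 84), abs=1e-12)
    assert res.n_genes == 10


def test_empty_or_degenerate_stratum_untestable():
    res = fisher_enrichment(0, 0, 5, 10)
    assert not res.testable and np.isnan(res.p_value) and res.stars == "ns"
    res = fisher_enrichment(3, 0, 7, 0)  # zero margin
    assert not res.testable


def test_variant_category_enrichment_with_exclusion():
    """20 outlier pairs (8 with category c), 1000 non-outlier pairs (40 with
    c), 30 pairs with other variants excluded first: OR = (8*960)/(12*40)."""
    outliers = {("g", f"o{i}") for i in range(20)}
    c_pairs = ({("g", f"o{i}") for i in range(8)}
               | {("g", f"n{i}") for i in range(40)})
    other = {("g", f"x{i}") for i in range(30)}
    universe = outliers | c_pairs | other | {("g", f"n{i}") for i in range(1000)}
    res = variant_category_enrichment(outliers, {"c": c_pairs, "other": other},
                                      universe)["c"]
    assert (res.a, res.b, res.c, res.d) == (8, 12, 40, 960)
    assert res.odds_ratio == pytest.approx(16.0)


def test_variant_enrichment_no_outlier_carriers():
    outliers = {("g", "o1"), ("g", "o2")}
    c_pairs = {("g", "n1"), ("g", "n2")}
    universe = outliers | c_pairs | {("g", f"n{i}") for i in range(3, 20)}
    res = variant_category_enrichment(outliers, {"c": c_pairs}, universe)["c"]
    assert res.a == 0 and res.odds_ratio < 1


def test_overlap_summary_set_arithmetic():
    pred = {("A", "s"), ("B", "s"), ("C", "s")}
    outl = {("B", "s"), ("C", "s"), ("D", "s")}
    out = overlap_summary(pred, outl, set())
    assert out["pred_and_outlier"] == 2
    assert out["confirmed_fraction"] == pytest.approx(2 / 3)
    assert overlap_summary(pred, set(), set())["pred_and_outlier"] == 0


def test_overlap_recovers_planted_link_rate():
    from txcensus.simulate import SimulationConfig, simulate_caller_outputs
    cfg = SimulationConfig(seed=13, n_genes=500, n_drivers=25,
                           splice_link_rate=0.5)
    tables, truth = simulate_caller_outputs(cfg)
    pred = set(zip(tables["splice_predictions"]["gene_id"],
                   tables["splice_predictions"]["sample_id"]))
    outl = set(zip(tables["splicing_outliers"]["gene_id"],
                   tables["splicing_outliers"]["sample_id"]))
    frac = overlap_summary(pred, outl, set())["confirmed_fraction"]
    n = len(pred)
    se = np.sqrt(0.5 * 0.5 / n)
    assert abs(frac - 0.5) < 4 * se + 0.02  # planted links + chance overlap


def _vc_inputs(z, preds):
    genes = ["g1"]
    corrected = pd.DataFrame([z], index=genes)
    predictors = {name: pd.DataFrame([v], index=genes)
                  for name, v in preds.items()}
    return corrected, predictors


def test_variance_components_single_predictor():
    z = [1.0, 2.0, 3.0, 4.0]
    preds = {"log_copy_ratio": [1.0, 2.0, 3.0, 4.0],
             "high_impact": [0.0] * 4, "promoter": [0.0] * 4,
             "structural": [0.0] * 4}
    vc = variance_components(*_vc_inputs(z, preds))
    assert vc.loc["g1", "log_copy_ratio"] == pytest.approx(1.0)
    assert vc.loc["g1"].sum() == pytest.approx(1.0)


def test_variance_components_orthogonal_equal_effects():
    """Two orthogonal predictors with equal effect and no noise split the
    explained variance 0.5/0.5 regardless of entry order."""
    x1 = np.array([1.0, 1.0, -1.0, -1.0])
    x2 = np.array([1.0, -1.0, 1.0, -1.0])
    z = x1 + x2
    preds = {"log_copy_ratio": x1, "high_impact": x2,
             "promoter": np.zeros(4), "structural": np.zeros(4)}
    vc = variance_components(*_vc_inputs(z, preds))
    assert vc.loc["g1", "log_copy_ratio"] == pytest.approx(0.5)
    assert vc.loc["g1", "high_impact"] == pytest.approx(0.5)


def test_variance_components_sum_to_one_with_noise():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(5)]
    n = 30
    corrected = pd.DataFrame(rng.normal(size=(5, n)), index=genes)
    predictors = {name: pd.DataFrame(rng.normal(size=(5, n)), index=genes)
                  for name in ("log_copy_ratio", "high_impact", "promoter",
                               "structural")}
    vc = variance_components(corrected, predictors)
    fracs = vc.drop(index="mean")
    assert np.allclose(fracs.sum(axis=1), 1.0)
    assert ((fracs >= 0) & (fracs <= 1)).all().all()
    vc_res = variance_components(corrected, predictors, include_residual=True)
    assert np.allclose(vc_res.drop(index="mean").sum(axis=1), 1.0)


def test_significance_stars_scale():
    assert [significance_stars(p) for p in (0.2, 0.05, 0.01, 0.001, 0.0001)] \
        == ["ns", "*", "**", "***", "****"]
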