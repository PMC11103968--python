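"""Recurrence-stratified driver-gene enrichment, variant-category enrichment
within outlier gene-sample pairs, caller-overlap summaries, and the
variance-component decomposition of corrected expression z-scores.

All 2x2 enrichments use Fisher's exact test.  Driver and variant-category
enrichments are two-sided; the odds ratio reported is the sample
(cross-product) estimate a*d / (b*c), with a 95% CI from the log-OR normal
approximation (0.5 added to every cell when any cell is zero).  Significance
stars follow the conventional scale: * p<=0.05, ** p<=0.01, *** p<=0.001,
**** p<=0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher enrichment.

    Table layout: a = in-group & annotated, b = in-group & not, c = out-group
    & annotated, d = out-group & not.  ``testable`` is False on degenerate
    tables (empty stratum or zero margin), in which case no p is emitted.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    n_genes: int = 0
    testable: bool = True

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.testable else "ns"


def fisher_enrichment(a: int, b: int, c: int, d: int, label: str = "",
                      alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher exact test plus sample OR and 95% log-normal CI."""
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 counts must be non-negative")
    n_genes = a + b
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return EnrichmentResult(label, a, b, c, d, n_genes=n_genes, testable=False)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = np.exp(np.log(orr) - 1.959963984540054 * se)
    ci_high = np.exp(np.log(orr) + 1.959963984540054 * se)
    point = (a * d) / (b * c) if b * c > 0 else orr
    return EnrichmentResult(label, a, b, c, d, point, ci_low, ci_high, p, n_genes)


def restrict_top_k_per_sample(calls: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Keep, per sample and category, the k most significant calls.

    Samples with many outliers (poor caller fit or globally perturbed
    regulation) dilute driver enrichment; restricting to the top-k most
    significant calls per sample concentrates it.  Ties are broken stably by
    (p ascending, |effect| descending, gene ID ascending).
    """
    if calls.empty:
        return calls.copy()
    ranked = calls.assign(_abs_effect=-calls["effect"].abs()).sort_values(
        ["sample_id", "category", "p_value", "_abs_effect", "gene_id"],
        kind="mergesort")
    out = ranked.groupby(["sample_id", "category"], sort=False).head(k)
    return out.drop(columns="_abs_effect").reset_index(drop=True)


def stratify_genes_by_recurrence(calls: pd.DataFrame,
                                 bins: tuple[int, ...] = (1, 5)) -> pd.DataFrame:
    """Assign each called gene, per category, to a recurrence stratum by the
    number of *distinct* samples in which it is called.

    Default bins (1, 5) produce the strata "1", "2-5", ">5".
    """
    if calls.empty:
        return pd.DataFrame(columns=["gene_id", "category", "n_samples", "stratum"])
    rec = (calls.groupby(["category", "gene_id"])["sample_id"].nunique()
           .rename("n_samples").reset_index())
    edges = sorted(bins)
    labels = []
    low = 1
    for e in edges:
        labels.append(str(low) if low == e else f"{low}-{e}")
        low = e + 1
    labels.append(f">{edges[-1]}")
    rec["stratum"] = pd.cut(rec["n_samples"],
                            bins=[0, *edges, np.inf], labels=labels).astype(str)
    return rec[["gene_id", "category", "n_samples", "stratum"]]


def driver_enrichment(strata: pd.DataFrame, ann: pd.DataFrame, role: str,
                      universe: set[str], category: str | None = None,
                      alternative: str = "two-sided") -> list[EnrichmentResult]:
    """Per-stratum Fisher enrichment of role-annotated driver genes.

    ``universe`` must be the genes the originating caller tested (common
    pool for expression outliers, rare pool for activation, spliced genes
    for splicing).  A gene is a role driver if ``is_driver_truth`` and
    ``role`` appears in its ``roles`` tag set.
    """
    if category is not None:
        strata = strata[strata["category"] == category]
    roles = ann["roles"].map(_tags)
    drivers = set(ann.index[(ann["is_driver_truth"].astype(bool))
                            & roles.map(lambda r: role in r)]) & universe
    results = []
    for stratum, sub in strata.groupby("stratum", sort=True):
        genes = set(sub["gene_id"]) & universe
        a = len(genes & drivers)
        b = len(genes - drivers)
        rest = universe - genes
        c = len(rest & drivers)
        d = len(rest - drivers)
        res = fisher_enrichment(a, b, c, d, label=str(stratum),
                                alternative=alternative)
        res.n_genes = len(genes)
        results.append(res)
    return results


def _tags(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {t for t in str(value).split(",") if t}


def variant_category_enrichment(outlier_pairs: set, variant_pairs: dict[str, set],
                                all_pairs: set,
                                alternative: str = "two-sided"
                                ) -> dict[str, EnrichmentResult]:
    """Enrichment of each variant category among outlier gene-sample pairs.

    For category c the universe is restricted to pairs that carry a
    category-c variant or no variant at all — pairs carrying only *other*
    variant categories are excluded so each test isolates one variant class.
    """
    any_variant = set().union(*variant_pairs.values()) if variant_pairs else set()
    results = {}
    for cat, pairs in variant_pairs.items():
        other = any_variant - pairs
        universe = all_pairs - other
        cat_pairs = pairs & universe
        out = outlier_pairs & universe
        a = len(out & cat_pairs)
        b = len(out - cat_pairs)
        c = len(cat_pairs - out)
        d = len(universe - out - cat_pairs)
        results[cat] = fisher_enrichment(a, b, c, d, label=cat,
                                         alternative=alternative)
    return results


def overlap_summary(splice_predictions: set, splicing_outliers: set,
                    vep_splice_pairs: set) -> dict:
    """Pairwise and three-way overlaps of splice evidence over (gene, sample)
    pairs, plus the fraction of genomic predictions confirmed by RNA-seq
    splicing outliers."""
    pred, outl, vep = map(set, (splice_predictions, splicing_outliers, vep_splice_pairs))
    pred_and_outl = pred & outl
    return {
        "n_predictions": len(pred),
        "n_outliers": len(outl),
        "n_vep": len(vep),
        "pred_and_outlier": len(pred_and_outl),
        "pred_and_vep": len(pred & vep),
        "outlier_and_vep": len(outl & vep),
        "three_way": len(pred & outl & vep),
        "confirmed_fraction": len(pred_and_outl) / len(pred) if pred else np.nan,
        "vep_confirmed_fraction": len(vep & outl) / len(vep) if vep else np.nan,
    }


PREDICTOR_ORDER = ("log_copy_ratio", "high_impact", "promoter", "structural")


def variance_components(corrected_z: pd.DataFrame, predictors: dict[str, pd.DataFrame],
                        order: tuple[str, ...] = PREDICTOR_ORDER,
                        include_residual: bool = False) -> pd.DataFrame:
    """Per-gene sequential (type-I) ANOVA of corrected expression z-scores on
    genomic predictors, fractions normalized to sum to one.

    For each gene an OLS model of z on the predictors is fitted in the given
    order; each predictor's component is its sequential sum of squares (the
    drop in residual SS when it enters).  Fractions are normalized over the
    predictors only (``include_residual=True`` adds the residual to the
    denominator instead).  Constant predictor columns contribute 0.  Returns
    one row per gene plus a ``mean`` row of per-predictor means across genes.
    """
    for name in order:
        if name not in predictors:
            raise ValueError(f"missing predictor: {name}")
    rows = {}
    for gene in corrected_z.index:
        y = corrected_z.loc[gene].to_numpy(dtype=float)
        if len(y) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 samples")
        X_cols = [predictors[name].loc[gene].to_numpy(dtype=float) for name in order]
        ss = _sequential_ss(y, X_cols)
        resid = float(np.sum((y - y.mean()) ** 2) - np.sum(ss))
        denom = np.sum(ss) + (max(resid, 0.0) if include_residual else 0.0)
        if denom <= 0:
            frac = np.zeros(len(order))
        else:
            frac = np.asarray(ss) / denom
        rows[gene] = dict(zip(order, frac))
        if include_residual:
            rows[gene]["residual"] = max(resid, 0.0) / denom if denom > 0 else 0.0
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.loc["mean"] = out.mean(axis=0)
    return out


def _sequential_ss(y: np.ndarray, X_cols: list[np.ndarray]) -> list[float]:
    """Sequential sums of squares via incremental least squares with an
    intercept always present."""
    n = len(y)
    X = np.ones((n, 1))
    prev_rss = float(np.sum((y - y.mean()) ** 2))
    ss = []
    for col in X_cols:
        if np.ptp(col) == 0:  # constant column: no additional fit, SS = 0
            ss.append(0.0)
            continue
        X = np.column_stack([X, col])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        ss.append(max(prev_rss - rss, 0.0))
        prev_rss = rss
    return ss
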