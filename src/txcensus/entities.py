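"""Disease-entity association of aberration calls and the validation-cohort
activation caller.

Gene-entity association asks, per gene and entity, whether the gene's calls
concentrate in that entity's samples: a one-sided Fisher exact test (greater)
on {in-entity vs not} x {called vs not} over samples, Benjamini-Hochberg
adjusted across all tests of the category.

The validation-cohort caller decides, per gene, which samples express it:
counts are normalized with median-of-ratios size factors, log2(x+1)
transformed, and fitted with a two-component equal-variance Gaussian mixture;
samples assigned to the higher-mean component are called activated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def associate_genes_entities(calls: pd.DataFrame, meta: pd.DataFrame,
                             category: str, fdr_level: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher association of every called gene with every entity.

    A gene is "called" in a sample if it has at least one call of the given
    category there (distinct samples; repeated calls count once).  Entities
    with zero samples are skipped with a warning.  Returns one row per
    (gene, entity) with the 2x2 counts, the one-sided p, the BH-adjusted p
    across all tests of this category, and the significance flag.
    """
    import logging
    sub = calls[calls["category"] == category]
    entity = meta["entity"]
    n_by_entity = entity.value_counts()
    empty = n_by_entity[n_by_entity == 0]
    if len(empty):
        logging.getLogger("txcensus").warning(
            "entities with no samples skipped: %s", list(empty.index))
    n_total = len(meta)
    called = sub.groupby("gene_id")["sample_id"].agg(set)
    rows = []
    for gene, samples in called.items():
        called_entities = entity.reindex(list(samples))
        counts_in = called_entities.value_counts()
        n_called = len(samples)
        for ent, n_ent in n_by_entity.items():
            a = int(counts_in.get(ent, 0))        # called, in entity
            b = n_called - a                      # called, elsewhere
            c = n_ent - a                         # not called, in entity
            d = n_total - n_ent - b               # not called, elsewhere
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((gene, ent, category, a, b, c, d, p))
    out = pd.DataFrame(rows, columns=["gene_id", "entity", "category",
                                      "a", "b", "c", "d", "p_value"])
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["adjusted_p"] = pd.Series(dtype=float)
    out["significant"] = out["adjusted_p"] < fdr_level
    return out.sort_values(["p_value", "gene_id", "entity"],
                           kind="mergesort").reset_index(drop=True)


def activation_fraction_by_entity(calls: pd.DataFrame, meta: pd.DataFrame,
                                  gene_id: str | None = None) -> pd.DataFrame:
    """Per-entity count and percentage of samples with an activation call.

    Fraction = distinct activated samples / entity size, reported as a
    percentage rounded to one decimal.
    """
    sub = calls[calls["category"] == "activation"]
    if gene_id is not None:
        sub = sub[sub["gene_id"] == gene_id]
    entity_sizes = meta["entity"].value_counts()
    activated = (sub.assign(entity=sub["sample_id"].map(meta["entity"]))
                 .groupby("entity")["sample_id"].nunique())
    out = pd.DataFrame({
        "n_samples": entity_sizes,
        "n_activated": activated.reindex(entity_sizes.index).fillna(0).astype(int),
    })
    out["percent"] = (100.0 * out["n_activated"] / out["n_samples"]).round(1)
    out.index.name = "entity"
    return out.sort_index()


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 estimator).

    The reference is the per-gene geometric mean across samples, taken over
    genes with nonzero counts in every sample; each sample's factor is the
    median of count/reference over those genes.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(arr[all_nonzero])
    log_geo_mean = logs.mean(axis=1)
    log_ratios = logs - log_geo_mean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class MixtureFit:
    """A fitted two-component equal-variance 1-D Gaussian mixture.

    ``activated`` marks samples hard-assigned to the higher-mean component.
    ``degenerate`` is set when the data carry no spread (all values equal) —
    no activation is reported in that case.
    """

    means: np.ndarray               # (2,), log scale, ascending
    variance: float                 # shared
    weight_high: float              # mixing weight of the higher-mean component
    posterior_high: np.ndarray      # per-sample P(higher-mean component)
    activated: np.ndarray           # boolean per sample
    log_likelihood: float
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False


def gmm_activation_call(normalized_counts, seed: int = 0, max_iter: int = 500,
                        tol: float = 1e-8) -> MixtureFit:
    """Call activated samples for one gene by equal-variance 2-component GMM
    on log2(normalized count + 1).

    EM with deterministic initialization: component means at the 10th and
    90th percentiles, equal weights, pooled variance.  Convergence when the
    log-likelihood gain drops below ``tol`` or after ``max_iter`` iterations.
    The seed parameter is accepted for interface stability; the fit itself
    is deterministic.
    """
    x = np.asarray(normalized_counts, dtype=float)
    if len(x) < 6:
        raise ValueError(f"need >= 6 samples, got {len(x)}")
    if (x < 0).any():
        raise ValueError("normalized counts must be non-negative")
    y = np.log2(x + 1.0)
    if np.ptp(y) == 0:
        return MixtureFit(means=np.array([y[0], y[0]]), variance=0.0,
                          weight_high=0.0, posterior_high=np.zeros(len(y)),
                          activated=np.zeros(len(y), bool),
                          log_likelihood=np.nan, degenerate=True)
    mu = np.percentile(y, [10.0, 90.0])
    if mu[0] == mu[1]:
        mu = np.array([y.min(), y.max()])
    var = max(float(np.var(y)), 1e-12)
    w = np.array([0.5, 0.5])
    ll_trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_dens = (-0.5 * np.log(2 * np.pi * var)
                    - (y[:, None] - mu[None, :]) ** 2 / (2 * var)
                    + np.log(w)[None, :])
        m = log_dens.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        resp = np.exp(log_dens - log_norm[:, None])
        ll = float(log_norm.sum())
        ll_trace.append(ll)
        if ll - prev_ll < tol:
            break
        prev_ll = ll
        # M step (shared variance pooled over both components)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        mu = (resp * y[:, None]).sum(axis=0) / nk
        var = float((resp * (y[:, None] - mu[None, :]) ** 2).sum() / len(y))
        var = max(var, 1e-12)
        w = nk / len(y)
    hi = int(np.argmax(mu))
    posterior_high = resp[:, hi]
    activated = posterior_high > 0.5
    order = np.argsort(mu)
    return MixtureFit(means=mu[order], variance=var, weight_high=float(w[hi]),
                      posterior_high=posterior_high, activated=activated,
                      log_likelihood=ll, ll_trace=np.asarray(ll_trace))
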