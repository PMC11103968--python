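"""NB-act: negative-binomial test for aberrant activation of rarely
expressed genes.

Expression-outlier callers built on count autoencoders require a gene to be
expressed in a reasonable fraction of the cohort to fit its distribution;
genes silent in almost every sample fall through.  NB-act closes that gap
with a parametric tail test.  For gene *g* in sample *s* with observed
fragment count *k*, the null hypothesis is that the gene is not expressed
beyond a baseline of 1 FPKM.  The implied null mean is

    mu = baseline_fpkm * length_bp[g] * library_size[s] / 1e9

and the p-value is the upper tail P(X >= k) of a negative binomial with mean
``mu`` and size (dispersion) parameter ``theta``, variance ``mu + mu^2 /
theta``.  The default ``theta = 0.02`` is deliberately small: a small size
parameter gives a heavy right tail, making the test conservative.

Genes are partitioned by FPKM into *common* (expressed above 1 FPKM in at
least 5% of samples — the domain of the autoencoder-based expression-outlier
caller), *rare* (above 1 FPKM in at least one but fewer than 5% of samples —
the NB-act domain), and *silent* (never above 1 FPKM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountsMatrix

CATEGORIES = ("underexpression", "overexpression", "activation",
              "splicing_over", "splicing_under", "splice_variant")

CALL_COLUMNS = ["gene_id", "sample_id", "category", "p_value", "adjusted_p", "effect"]


@dataclass(frozen=True)
class NBActParams:
    """Null model of the activation test.

    baseline_fpkm : expected expression of a non-expressed gene (default 1,
        the FPKM threshold separating expressed from non-expressed genes).
    dispersion : NB size parameter theta (default 0.02; variance mu +
        mu^2/theta, so smaller theta means a heavier, more conservative tail).
    fdr_level : Benjamini-Hochberg level for calling activation outliers.
    """

    baseline_fpkm: float = 1.0
    dispersion: float = 0.02
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_fpkm <= 0:
            raise ValueError("baseline_fpkm must be positive")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


def compute_fpkm(counts: CountsMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * library_size[s]).
    """
    lengths = ann["length_bp"].reindex(counts.genes)
    if lengths.isna().any():
        missing = counts.genes[lengths.isna()].tolist()
        raise ValueError(f"genes missing length annotation: {missing}")
    if (lengths <= 0).any() or (counts.library_size <= 0).any():
        raise ValueError("gene lengths and library sizes must be positive")
    k = counts.counts.to_numpy(dtype=float)
    fpkm = k * 1e9 / np.outer(lengths.to_numpy(dtype=float),
                              counts.library_size.to_numpy(dtype=float))
    return pd.DataFrame(fpkm, index=counts.genes, columns=counts.samples)


def partition_genes(fpkm: pd.DataFrame, threshold: float = 1.0,
                    common_fraction: float = 0.05) -> pd.Series:
    """Assign each gene to {common, rare, silent} by cohort-wide FPKM.

    common: FPKM > threshold in at least ceil(common_fraction * n) samples;
    rare: in at least one but fewer samples than that bound; silent: never.
    Requires >= 20 samples (below this the 5% rule degenerates).
    """
    n = fpkm.shape[1]
    if n < 20:
        raise ValueError(f"partition requires >= 20 samples, got {n}")
    n_expr = (fpkm > threshold).sum(axis=1)
    bound = int(np.ceil(common_fraction * n))
    out = pd.Series("silent", index=fpkm.index, name="pool")
    out[n_expr >= bound] = "common"
    out[(n_expr >= 1) & (n_expr < bound)] = "rare"
    return out


def nbact_pvalue(k, length_bp, library_size, params: NBActParams = NBActParams()):
    """Upper-tail NB p-value P(X >= k) under the activation null.

    Accepts scalars or broadcastable arrays; k must be non-negative
    integer(s).  Numerically stable via the survival function (no explicit
    pmf summation), valid for k up to at least 1e6.
    """
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.all(np.equal(np.mod(k, 1), 0)):
            raise ValueError("observed fragment counts must be integers")
        k = k.astype(np.int64)
    if (k < 0).any():
        raise ValueError("observed fragment counts must be non-negative")
    mu = params.baseline_fpkm * np.asarray(length_bp, dtype=float) \
        * np.asarray(library_size, dtype=float) / 1e9
    theta = params.dispersion
    # scipy's nbinom(n, p): mean n(1-p)/p; matching mean mu, size theta
    p_param = theta / (theta + mu)
    # P(X >= k) = sf(k - 1); sf(-1) = 1 exactly
    out = stats.nbinom.sf(k - 1, theta, p_param)
    return out if out.ndim else float(out)


def call_activation_outliers(counts: CountsMatrix, ann: pd.DataFrame,
                             params: NBActParams = NBActParams(),
                             pools: pd.Series | None = None,
                             adjust_scope: str = "global") -> pd.DataFrame:
    """Run NB-act on every rare gene x sample and call activation outliers.

    P-values are BH-adjusted — by default jointly across all rare-gene x
    sample tests (``adjust_scope="global"``), optionally per sample — and
    calls are made at adjusted p < ``params.fdr_level``.  Returns an
    aberration-call table (category ``activation``; effect = fragment count)
    with one row per significant gene-sample pair, sorted by p.
    """
    if pools is None:
        fpkm = compute_fpkm(counts, ann)
        pools = partition_genes(fpkm)
    rare = pools.index[pools == "rare"]
    if len(rare) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    k = counts.counts.loc[rare]
    lengths = ann["length_bp"].reindex(rare).to_numpy(dtype=float)
    lib = counts.library_size.to_numpy(dtype=float)
    pmat = nbact_pvalue(k.to_numpy(), lengths[:, None], lib[None, :], params)
    long = pd.DataFrame({
        "gene_id": np.repeat(rare.to_numpy(), len(counts.samples)),
        "sample_id": np.tile(counts.samples.to_numpy(), len(rare)),
        "p_value": pmat.ravel(),
        "effect": k.to_numpy().ravel().astype(float),
    })
    if adjust_scope == "global":
        long["adjusted_p"] = multipletests(long["p_value"], method="fdr_bh")[1]
    elif adjust_scope == "per_sample":
        long["adjusted_p"] = long.groupby("sample_id")["p_value"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1])
    else:
        raise ValueError(f"unknown adjust_scope: {adjust_scope!r}")
    calls = long[long["adjusted_p"] < params.fdr_level].copy()
    calls["category"] = "activation"
    calls = calls[CALL_COLUMNS].sort_values(
        ["p_value", "gene_id", "sample_id"], kind="mergesort")
    return calls.reset_index(drop=True)


def harmonize_caller_calls(expression_calls: pd.DataFrame,
                           splicing_calls: pd.DataFrame,
                           fdr_level: float = 0.05) -> pd.DataFrame:
    """Unify external expression/splicing outlier tables into aberration calls.

    Significant expression outliers (adjusted p < fdr) are split by the sign
    of the z-score into under/overexpression; splicing outliers by the sign
    of the delta Intron Jaccard Index into splicing_under/splicing_over.  A
    significant call with exactly zero effect has no direction and is
    dropped with a warning (the callers' null — it carries no usable sign).
    """
    import logging
    out = []
    sig = expression_calls[expression_calls["adjusted_p"] < fdr_level]
    zero = sig["z_score"] == 0
    if zero.any():
        logging.getLogger("txcensus").warning(
            "%d significant expression calls with z == 0 dropped", int(zero.sum()))
    sig = sig[~zero]
    out.append(pd.DataFrame({
        "gene_id": sig["gene_id"], "sample_id": sig["sample_id"],
        "category": np.where(sig["z_score"] < 0, "underexpression", "overexpression"),
        "p_value": sig["p_value"], "adjusted_p": sig["adjusted_p"],
        "effect": sig["z_score"],
    }))
    sig = splicing_calls[splicing_calls["adjusted_p"] < fdr_level]
    zero = sig["delta_jaccard"] == 0
    if zero.any():
        logging.getLogger("txcensus").warning(
            "%d significant splicing calls with delta == 0 dropped", int(zero.sum()))
    sig = sig[~zero]
    out.append(pd.DataFrame({
        "gene_id": sig["gene_id"], "sample_id": sig["sample_id"],
        "category": np.where(sig["delta_jaccard"] > 0, "splicing_over", "splicing_under"),
        "p_value": sig["p_value"], "adjusted_p": sig["adjusted_p"],
        "effect": sig["delta_jaccard"],
    }))
    res = pd.concat(out, ignore_index=True)
    return res[CALL_COLUMNS].reset_index(drop=True)
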