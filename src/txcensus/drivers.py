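"""Gene-level feature matrix and cross-validated driver-gene classifier.

Each gene gets an 85-dimensional feature vector summarizing every aberration
source: 21 mutational-recurrence features (3 summaries x 7 tools), 9
splice-prediction features (sample counts over a score-cutoff grid), 22
expression-outlier features (sample counts over direction x significance x
effect-size cutoffs), 11 activation features, and 22 splicing-outlier
features.  The block grids are configuration; the shipped defaults are the
package's own and are documented in the methods note.

A random forest (min_samples_split=19, max_depth=10, defaults otherwise) is
trained with stratified five-fold cross-validation, repeated with 10 seeds;
performance is average precision on the validation folds, and only
out-of-fold predicted probabilities (averaged over repeats) are used for
ranking candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .enrichment import EnrichmentResult, fisher_enrichment
from .simulate import RECURRENCE_TOOLS


@dataclass
class FeatureConfig:
    """Grids behind each feature block; block dimensions must match the
    declared layout (21 + 9 + 22 + 11 + 22 = 85 by default)."""

    recurrence_tools: tuple[str, ...] = RECURRENCE_TOOLS
    recurrence_summaries: tuple[str, ...] = ("score", "q_value", "rank")
    splice_pred_cutoffs: tuple[float, ...] = (
        0.01, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95)
    expression_z_cutoffs: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0)
    splicing_delta_cutoffs: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3)
    activation_effect_cutoffs: tuple[float, ...] = (
        0.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0)
    nominal_p: float = 0.05
    adjusted_p: float = 0.05

    @property
    def block_dims(self) -> dict[str, int]:
        return {
            "recurrence": len(self.recurrence_tools) * len(self.recurrence_summaries),
            "splice_pred": len(self.splice_pred_cutoffs),
            "expression": 4 * len(self.expression_z_cutoffs) + 2,
            "activation": len(self.activation_effect_cutoffs) + 1,
            "splicing": 4 * len(self.splicing_delta_cutoffs) + 2,
        }

    @property
    def n_features(self) -> int:
        return sum(self.block_dims.values())


@dataclass
class CVResult:
    """Cross-validation output: per-repeat x per-fold average precision and
    out-of-fold probabilities (one column per repeat; every gene is scored
    in exactly one validation fold per repeat)."""

    average_precision: pd.DataFrame     # rows: repeats, cols: folds
    oof_probability: pd.DataFrame       # rows: genes, cols: repeats
    repeat_seeds: list[int]
    labels: pd.Series

    @property
    def mean_ap(self) -> float:
        return float(self.average_precision.to_numpy().mean())

    @property
    def mean_oof(self) -> pd.Series:
        return self.oof_probability.mean(axis=1)


def _directional_counts(events: pd.DataFrame, effect_col: str,
                        cutoffs: tuple[float, ...], cfg: FeatureConfig,
                        genes: pd.Index, prefix: str) -> pd.DataFrame:
    """Counts of calling samples over {up,down} x {nominal,adjusted} x
    |effect| cutoff grids, plus nominal/adjusted totals (dimension 4*c+2)."""
    cols = {}
    nominal = events["p_value"] < cfg.nominal_p
    adjusted = events["adjusted_p"] < cfg.adjusted_p
    up = events[effect_col] > 0
    for sig_name, sig in (("nom", nominal), ("adj", adjusted)):
        for dir_name, d in (("up", up), ("down", ~up)):
            for c in cutoffs:
                mask = sig & d & (events[effect_col].abs() >= c)
                counts = (events[mask].groupby("gene_id")["sample_id"].nunique())
                cols[f"{prefix}_{dir_name}_{sig_name}_ge{c:g}"] = counts
    cols[f"{prefix}_total_nom"] = events[nominal].groupby("gene_id")["sample_id"].nunique()
    cols[f"{prefix}_total_adj"] = events[adjusted].groupby("gene_id")["sample_id"].nunique()
    return pd.DataFrame(cols, index=genes).fillna(0.0)


def build_feature_matrix(tables: dict[str, pd.DataFrame], labels: pd.Series,
                         cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Assemble the gene x feature matrix; absence of events encodes as 0.

    ``tables`` carries recurrence, splice_predictions, expression_outliers,
    activation_outliers, splicing_outliers; ``labels`` is the driver truth
    (index = gene universe).  Raises if a block's realized width differs
    from its declared dimension.
    """
    genes = labels.index
    blocks: dict[str, pd.DataFrame] = {}

    rec = tables["recurrence"]
    wide = {}
    for tool in cfg.recurrence_tools:
        sub = rec[rec["tool"] == tool].set_index("gene_id")
        for summary in cfg.recurrence_summaries:
            col = sub[summary].reindex(genes)
            if summary == "rank":  # missing gene: worst rank
                col = col.fillna(float(len(genes)))
            elif summary == "q_value":
                col = col.fillna(1.0)
            else:
                col = col.fillna(0.0)
            wide[f"rec_{tool}_{summary}"] = col
    blocks["recurrence"] = pd.DataFrame(wide, index=genes)

    pred = tables["splice_predictions"]
    cols = {}
    for c in cfg.splice_pred_cutoffs:
        counts = pred[pred["score"] >= c].groupby("gene_id")["sample_id"].nunique()
        cols[f"pred_ge{c:g}"] = counts
    blocks["splice_pred"] = pd.DataFrame(cols, index=genes).fillna(0.0)

    blocks["expression"] = _directional_counts(
        tables["expression_outliers"], "z_score", cfg.expression_z_cutoffs,
        cfg, genes, "expr")

    act = tables["activation_outliers"]
    adj = act[act["adjusted_p"] < cfg.adjusted_p]
    cols = {}
    for c in cfg.activation_effect_cutoffs:
        counts = adj[adj["effect"] >= c].groupby("gene_id")["sample_id"].nunique()
        cols[f"act_adj_ge{c:g}"] = counts
    cols["act_total_nom"] = (act[act["p_value"] < cfg.nominal_p]
                             .groupby("gene_id")["sample_id"].nunique())
    blocks["activation"] = pd.DataFrame(cols, index=genes).fillna(0.0)

    blocks["splicing"] = _directional_counts(
        tables["splicing_outliers"], "delta_jaccard", cfg.splicing_delta_cutoffs,
        cfg, genes, "spl")

    for name, block in blocks.items():
        expected = cfg.block_dims[name]
        if block.shape[1] != expected:
            raise ValueError(f"block {name!r}: {block.shape[1]} features, "
                             f"declared {expected}")
    out = pd.concat(blocks.values(), axis=1)
    out["label"] = labels.reindex(genes).astype(bool)
    return out


FEATURE_BLOCK_PREFIXES = {"recurrence": "rec_", "splice_pred": "pred_",
                          "expression": "expr_", "activation": "act_",
                          "splicing": "spl_"}


def ablate_block(features: pd.DataFrame, block: str) -> pd.DataFrame:
    """Drop one feature block (for cumulative-feature / ablation analyses)."""
    prefix = FEATURE_BLOCK_PREFIXES[block]
    keep = [c for c in features.columns if not c.startswith(prefix)]
    return features[keep]


def train_evaluate_cv(features: pd.DataFrame, seed: int = 0, n_repeats: int = 10,
                      n_folds: int = 5, min_samples_split: int = 19,
                      max_depth: int = 10, n_estimators: int = 100) -> CVResult:
    """Repeated stratified cross-validation of the random-forest classifier.

    Stratification preserves the positive-class fraction in every fold; a
    fold without both classes aborts with a stratification report.  Repeat
    seeds derive deterministically from ``seed``.
    """
    y = features["label"].astype(int).to_numpy()
    X = features.drop(columns="label").to_numpy(dtype=float)
    n_pos = int(y.sum())
    if n_pos < n_folds * 2:
        raise ValueError(f"need >= 2 positives per fold: {n_pos} positives, "
                         f"{n_folds} folds")
    repeat_seeds = [int(seed + 1000 * r) for r in range(n_repeats)]
    ap = np.zeros((n_repeats, n_folds))
    oof = np.zeros((len(y), n_repeats))
    for r, rs in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for f, (train, test) in enumerate(skf.split(X, y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise ValueError(
                    f"single-class fold: repeat {r}, fold {f}, "
                    f"train positives {int(y[train].sum())}, "
                    f"test positives {int(y[test].sum())}")
            clf = RandomForestClassifier(
                n_estimators=n_estimators, min_samples_split=min_samples_split,
                max_depth=max_depth, random_state=rs, n_jobs=1)
            clf.fit(X[train], y[train])
            prob = clf.predict_proba(X[test])[:, 1]
            ap[r, f] = average_precision_score(y[test], prob)
            oof[test, r] = prob
    return CVResult(
        average_precision=pd.DataFrame(
            ap, index=[f"repeat{r}" for r in range(n_repeats)],
            columns=[f"fold{f}" for f in range(n_folds)]),
        oof_probability=pd.DataFrame(
            oof, index=features.index,
            columns=[f"repeat{r}" for r in range(n_repeats)]),
        repeat_seeds=repeat_seeds,
        labels=features["label"])


def rank_genes(cv: CVResult, ann: pd.DataFrame, k: int = 100):
    """Rank genes by mean out-of-fold probability and categorize the top k.

    Categories: "reported hematologic driver" (truth driver with hematologic
    tissue annotation), "reported cancer driver" (truth driver without it),
    "candidate" otherwise.  Also returns the Fisher enrichment of truth
    drivers among the top k against the whole universe.
    """
    if k > len(cv.mean_oof):
        raise ValueError(f"k={k} exceeds {len(cv.mean_oof)} genes")
    prob = cv.mean_oof.rename("probability")
    # sort by gene id first so the stable sort breaks probability ties
    # lexicographically
    ranked = prob.to_frame().sort_index(kind="mergesort").sort_values(
        "probability", ascending=False, kind="mergesort")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    is_driver = ann["is_driver_truth"].reindex(ranked.index).fillna(False).astype(bool)
    hema = ann["tissue_types"].reindex(ranked.index).fillna("").str.contains("L")
    ranked["category"] = np.where(
        is_driver & hema, "reported hematologic driver",
        np.where(is_driver, "reported cancer driver", "candidate"))
    top = ranked.head(k)
    a = int((top["category"] != "candidate").sum())
    b = k - a
    c = int(is_driver.sum()) - a
    d = len(ranked) - k - c
    enr = fisher_enrichment(a, b, c, d, label=f"top{k}")
    return ranked, enr
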