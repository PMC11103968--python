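"""Synthetic cohort generator with planted ground truth.

The real cohort (thousands of leukemia/lymphoma transcriptomes with matched
genomes) is access-restricted, so every pipeline input is emulated here with
known ground truth: a negative-binomial fragment-count matrix with planted
activations of rarely expressed genes, variant tables spanning every filter
branch, external-caller output tables in which planted driver genes carry
elevated signal, and a small validation cohort drawn from a two-component
log-scale Gaussian mixture.

The default entity table is a six-entity miniature of the study design —
three myeloid and three mature-B-cell entities, including a rare HCL-V-like
entity of 29 samples — so entity-association behaviour can be exercised at
desk scale.  Library sizes are drawn log-uniformly over [1e7, 1e8], typical
of total-RNA-seq depth.  Counts use the NB size parameterization (variance
mu + mu^2/theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountsMatrix

DEFAULT_ENTITIES = {
    # entity: (n_samples, study_group, lineage)
    "AML": (100, "AML", "myeloid"),
    "MDS": (80, "MDS", "myeloid"),
    "CMML": (50, "CMML", "myeloid"),
    "MZL": (71, "MatureB", "lymphatic"),
    "HCL": (68, "HairyCell", "lymphatic"),
    "HCL-V": (29, "HairyCell", "lymphatic"),
}

FEATURE_BLOCKS = ("recurrence", "splice_pred", "expression", "activation", "splicing")

RECURRENCE_TOOLS = ("clustl", "hotmaps", "smregions", "cbase", "mutpanning",
                    "dndscv", "fml")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Counts: ``n_genes`` genes split into a commonly expressed pool (fraction
    ``common_fraction``) and a rarely expressed pool.  Common genes express
    around ``common_mean_fpkm``; rare genes are silent except in a handful
    of samples where they express at ``rare_expressed_fpkm`` (enough to
    clear the 1-FPKM threshold, not enough to look activated).  Planted
    activations express at ``activation_fpkm`` (must exceed 1 FPKM to be
    distinguishable from baseline).  ``dispersion`` is the NB size theta of
    the generator (not of the test's null).
    """

    seed: int = 0
    entities: dict = field(default_factory=lambda: dict(DEFAULT_ENTITIES))
    n_genes: int = 1000
    common_fraction: float = 0.5
    common_mean_fpkm: float = 5.0
    rare_expressed_fpkm: float = 3.0
    rare_expressed_rate: float = 0.01   # fraction of samples where a rare gene expresses
    activation_fpkm: float = 1000.0
    n_planted_activations: int = 0
    dispersion: float = 10.0
    lib_size_range: tuple[float, float] = (1e7, 1e8)
    # driver planting for caller-output simulation
    n_drivers: int = 50
    signal_strength: dict = field(default_factory=lambda: {
        "recurrence": 5.0, "splice_pred": 5.0, "expression": 5.0,
        "activation": 5.0, "splicing": 5.0})
    base_event_rate: float = 0.5        # Poisson mean of events per non-driver gene
    splice_link_rate: float = 0.5       # fraction of splice predictions with a matching outlier
    # variant fixture
    n_variants_per_branch: int = 2
    # validation cohort
    validation_entities: dict = field(default_factory=lambda: {"HCL-V": 14, "HCL": 28})
    validation_n_activated: dict = field(default_factory=lambda: {"HCL-V": 5, "HCL": 5})
    mixture_means: tuple[float, float] = (1.0, 6.0)
    mixture_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.activation_fpkm <= 1:
            raise ValueError("activation_fpkm must exceed 1 FPKM "
                             "(indistinguishable from baseline otherwise)")
        if self.mixture_means[0] == self.mixture_means[1]:
            raise ValueError("degenerate mixture: component means are equal")


@dataclass
class GroundTruth:
    """Planted events; every generated event appears in exactly one table."""

    activations: pd.DataFrame = field(default_factory=pd.DataFrame)
    driver_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    small_variant_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    sv_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_links: pd.DataFrame = field(default_factory=pd.DataFrame)
    validation_membership: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for entity, (n, group, lineage) in cfg.entities.items():
        for i in range(n):
            rows.append((f"{entity}_{i:04d}", entity, group, lineage))
    df = pd.DataFrame(rows, columns=["sample_id", "entity", "study_group", "lineage"])
    return df.set_index("sample_id", drop=False)


def gene_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene models: lengths log-uniform 0.5-50 kb, laid end to
    end on one synthetic chromosome; drivers are the first ``n_drivers``
    gene IDs after a seeded shuffle."""
    rng = np.random.default_rng(cfg.seed + 101)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    lengths = np.exp(rng.uniform(np.log(500), np.log(50_000), cfg.n_genes)).astype(int)
    starts = np.concatenate([[0], np.cumsum(lengths + 10_000)[:-1]])
    strands = rng.choice(["+", "-"], cfg.n_genes)
    drivers = rng.permutation(cfg.n_genes)[:cfg.n_drivers]
    is_driver = np.zeros(cfg.n_genes, bool)
    is_driver[drivers] = True
    roles = np.where(is_driver,
                     rng.choice(["oncogene", "TSG", "oncogene,TSG"], cfg.n_genes),
                     "")
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "length_bp": lengths,
        "chrom": "chrS",
        "start": starts,
        "end": starts + lengths,
        "tss": np.where(strands == "+", starts, starts + lengths),
        "strand": strands,
        "is_driver_truth": is_driver,
        "tissue_types": np.where(is_driver, "L", ""),
        "roles": roles,
    })
    return df.set_index("gene_id", drop=False)


def _nb_draw(rng: np.random.Generator, mean, theta):
    """NB(mean, size theta) via gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def simulate_counts(cfg: SimulationConfig):
    """Generate the fragment-count matrix and planted-activation truth.

    Common genes draw NB counts at their gene mean FPKM in every sample.
    Rare genes are silent (mean ~0) except in a seeded subset of samples
    where they express at ``rare_expressed_fpkm``; planted activations
    overwrite ``n_planted_activations`` rare-gene x sample cells at
    ``activation_fpkm``.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = gene_annotation(cfg)
    meta = sample_metadata(cfg)
    n_samples = len(meta)
    lo, hi = cfg.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples)).astype(np.int64)
    lengths = ann["length_bp"].to_numpy(dtype=float)

    n_common = int(round(cfg.common_fraction * cfg.n_genes))
    is_common = np.zeros(cfg.n_genes, bool)
    is_common[:n_common] = True

    # per-gene mean FPKM
    fpkm_mean = np.zeros((cfg.n_genes, n_samples))
    common_base = cfg.common_mean_fpkm * np.exp(rng.normal(0, 0.5, n_common))
    fpkm_mean[is_common] = common_base[:, None]
    # rare genes: a few expressing samples each
    rare_idx = np.where(~is_common)[0]
    n_expr = max(1, int(round(cfg.rare_expressed_rate * n_samples)))
    for g in rare_idx:
        chosen = rng.choice(n_samples, size=n_expr, replace=False)
        fpkm_mean[g, chosen] = cfg.rare_expressed_fpkm

    # planted activations on rare genes
    planted = []
    if cfg.n_planted_activations > 0:
        cells = rng.choice(len(rare_idx) * n_samples,
                           size=cfg.n_planted_activations, replace=False)
        for cell in cells:
            g = rare_idx[cell // n_samples]
            s = cell % n_samples
            fpkm_mean[g, s] = cfg.activation_fpkm
            planted.append((ann.index[g], meta.index[s], cfg.activation_fpkm))

    mu = fpkm_mean * lengths[:, None] * lib[None, :] / 1e9
    counts = np.zeros_like(mu, dtype=np.int64)
    nonzero = mu > 0
    counts[nonzero] = _nb_draw(rng, mu[nonzero], cfg.dispersion)

    cm = CountsMatrix(
        counts=pd.DataFrame(counts, index=ann.index, columns=meta.index),
        library_size=pd.Series(lib, index=meta.index))
    truth = GroundTruth(
        activations=pd.DataFrame(planted,
                                 columns=["gene_id", "sample_id", "effect_fpkm"]),
        driver_labels=ann["is_driver_truth"].copy())
    return cm, truth


# ---------------------------------------------------------------------------
# variant fixture: spans every filter branch with truth by construction

def simulate_variants(cfg: SimulationConfig):
    """Emit small-variant / SV / segment tables crossing every filter branch.

    Truth encodes, per variant, whether it should survive each cascade under
    the boundary rulings (keep at MAF exactly 0.05%, at VAF exactly 0.1 and
    0.15; SV recurrence dropped only when both lineage counts reach 4).
    Truth flags are written at construction from the branch levels, not by
    running the filters.
    """
    rng = np.random.default_rng(cfg.seed + 202)
    meta = sample_metadata(cfg)
    ann = gene_annotation(cfg)
    samples = meta.index.to_numpy()
    genes = ann.index.to_numpy()

    filter_levels = ["PASS", "LowQual"]
    af_levels = [0.0004, 0.0005, 0.0006, np.nan]
    vaf_levels = [0.09, 0.10, 0.12, 0.15, 0.5]
    read_levels = [19, 20, 40]
    consequence_levels = [
        ("HIGH", "stop_gained"),
        ("MODERATE", "missense_variant"),
        ("LOW", "splice_region_variant"),
        ("MODIFIER", "5_prime_UTR_variant"),
        ("MODIFIER", "intergenic_variant"),
    ]
    rows = []
    vid = 0
    for f in filter_levels:
        for af in af_levels:
            for vaf in vaf_levels:
                for reads in read_levels:
                    for impact, cons in consequence_levels:
                        for _ in range(cfg.n_variants_per_branch):
                            g = genes[rng.integers(len(genes))]
                            s = samples[rng.integers(len(samples))]
                            tss = ann.loc[g, "tss"]
                            pos = int(tss + rng.integers(-5000, 5000))
                            pass1 = (f == "PASS"
                                     and (np.isnan(af) or af <= 0.0005)
                                     and vaf >= 0.1)
                            pass2 = (pass1 and vaf >= 0.15 and reads >= 20
                                     and (impact in ("HIGH", "MODERATE", "LOW")
                                          or cons in ("5_prime_UTR_variant",
                                                      "3_prime_UTR_variant",
                                                      "coding_sequence_variant")))
                            rows.append((f"v{vid:05d}", s, g, pos, f, af, vaf,
                                         reads, cons, impact, pass1, pass2))
                            vid += 1
    cols = ["variant_id", "sample_id", "gene_id", "position", "filter_status",
            "gnomad_af", "vaf", "read_support", "consequences", "impact",
            "survives_filter", "survives_recurrence_filter"]
    small = pd.DataFrame(rows, columns=cols)
    small_truth = small[["variant_id", "survives_filter", "survives_recurrence_filter"]]
    small_variants = small.drop(columns=["survives_filter",
                                         "survives_recurrence_filter"])

    # SV branches
    myeloid = [e for e, (_, _, lin) in cfg.entities.items() if lin == "myeloid"]
    lymphatic = [e for e, (_, _, lin) in cfg.entities.items() if lin == "lymphatic"]
    sv_rows = []
    svid = 0
    for f in ["PASS", "LowQual"]:
        for support in [2, 3, 5]:
            for known in [False, True]:
                for n_my, n_ly in [(0, 0), (4, 3), (3, 4),
                                   (min(4, len(myeloid)), min(4, len(lymphatic)))]:
                    for _ in range(cfg.n_variants_per_branch):
                        occ = {}
                        for e in myeloid[:n_my]:
                            occ.setdefault("myeloid", {})[e] = int(rng.integers(1, 4))
                        for e in lymphatic[:n_ly]:
                            occ.setdefault("lymphatic", {})[e] = int(rng.integers(1, 4))
                        occ_str = ";".join(
                            f"{lin}:{e}={c}" for lin, d in occ.items()
                            for e, c in d.items())
                        keeps = (f == "PASS" and support >= 3 and not known
                                 and not (n_my >= 4 and n_ly >= 4))
                        sv_rows.append((f"sv{svid:05d}",
                                        samples[rng.integers(len(samples))],
                                        genes[rng.integers(len(genes))],
                                        f, support, known, occ_str, keeps))
                        svid += 1
    sv = pd.DataFrame(sv_rows, columns=["variant_id", "sample_id", "gene_id",
                                        "filter_status", "paired_read_support",
                                        "gnomad_sv_exact_match",
                                        "entity_occurrence", "survives_filter"])
    sv_truth = sv[["variant_id", "survives_filter"]]
    sv_table = sv.drop(columns=["survives_filter"])

    # copy-ratio segments: per sample a gain, a loss, and a neutral block
    span = int(ann["end"].max())
    seg_rows = []
    for s in samples[: min(20, len(samples))]:
        edges = np.sort(rng.choice(span, size=4, replace=False))
        calls = rng.permutation(["+", "-", "0"])
        bounds = [0, *edges.tolist(), span]
        for i, call in enumerate(calls):
            lcr = {"+": 0.6, "-": -0.6, "0": 0.0}[call] + rng.normal(0, 0.05)
            seg_rows.append((s, "chrS", bounds[i], bounds[i + 1], call, lcr))
    segments = pd.DataFrame(seg_rows, columns=["sample_id", "chrom", "start",
                                               "end", "call", "log_copy_ratio"])

    truth = GroundTruth(small_variant_truth=small_truth, sv_truth=sv_truth)
    return small_variants, sv_table, segments, truth


# ---------------------------------------------------------------------------
# external caller outputs with planted driver signal

def simulate_caller_outputs(cfg: SimulationConfig):
    """Emulate the output tables of the external callers.

    Planted driver genes carry elevated signal in every block whose
    ``signal_strength`` is positive; non-drivers carry exchangeable noise.
    Event counts per gene are Poisson(base + signal * is_driver); p-values
    of recurrence tools are U(0,1)^(1 + signal) for drivers.  A configurable
    fraction of splice-variant predictions is linked to a matching splicing
    outlier (recorded in truth as causal links).
    """
    rng = np.random.default_rng(cfg.seed + 303)
    ann = gene_annotation(cfg)
    meta = sample_metadata(cfg)
    genes = ann.index.to_numpy()
    samples = meta.index.to_numpy()
    is_driver = ann["is_driver_truth"].to_numpy()
    s = cfg.signal_strength

    # gene-level mutational-recurrence metrics, one row per gene x tool
    from statsmodels.stats.multitest import multipletests
    rec_rows = []
    for tool in RECURRENCE_TOOLS:
        u = rng.uniform(size=len(genes))
        p = np.where(is_driver, u ** (1.0 + s["recurrence"]), u)
        q = multipletests(p, method="fdr_bh")[1]
        rank = np.argsort(np.argsort(p)) + 1
        rec_rows.append(pd.DataFrame({
            "gene_id": genes, "tool": tool, "score": -np.log10(np.maximum(p, 1e-300)),
            "p_value": p, "q_value": q, "rank": rank}))
    recurrence = pd.concat(rec_rows, ignore_index=True)

    def _events(block: str) -> pd.DataFrame:
        lam = cfg.base_event_rate + s[block] * is_driver
        n_events = rng.poisson(lam)
        g_idx = np.repeat(np.arange(len(genes)), n_events)
        s_idx = rng.integers(len(samples), size=len(g_idx))
        return pd.DataFrame({"gene_id": genes[g_idx], "sample_id": samples[s_idx]})

    expr = _events("expression")
    expr["z_score"] = rng.normal(0, 1, len(expr)) + rng.choice([-4, 4], len(expr))
    expr["p_value"] = 10.0 ** rng.uniform(-8, -3, len(expr))
    expr["adjusted_p"] = np.minimum(expr["p_value"] * 50, 0.049)
    expr["fold_change"] = 2.0 ** np.sign(expr["z_score"])
    expr["corrected_z"] = expr["z_score"]

    spl = _events("splicing")
    spl["delta_jaccard"] = rng.uniform(0.05, 0.6, len(spl)) * rng.choice([-1, 1], len(spl))
    spl["p_value"] = 10.0 ** rng.uniform(-8, -3, len(spl))
    spl["adjusted_p"] = np.minimum(spl["p_value"] * 50, 0.049)

    act = _events("activation")
    act["p_value"] = 10.0 ** rng.uniform(-10, -4, len(act))
    act["adjusted_p"] = np.minimum(act["p_value"] * 50, 0.049)
    act["effect"] = rng.integers(50, 5000, len(act)).astype(float)

    pred = _events("splice_pred")
    pred["variant_id"] = [f"sv_pred{i:06d}" for i in range(len(pred))]
    pred["score"] = rng.uniform(0.2, 1.0, len(pred))

    # causal links: a fraction of predictions also appear as splicing outliers
    linked = pred[rng.uniform(size=len(pred)) < cfg.splice_link_rate]
    if len(linked):
        extra = linked[["gene_id", "sample_id"]].copy()
        extra["delta_jaccard"] = rng.uniform(0.1, 0.6, len(extra))
        extra["p_value"] = 10.0 ** rng.uniform(-8, -3, len(extra))
        extra["adjusted_p"] = np.minimum(extra["p_value"] * 50, 0.049)
        spl = pd.concat([spl, extra], ignore_index=True)
    links = linked[["gene_id", "sample_id", "variant_id"]].reset_index(drop=True)

    truth = GroundTruth(driver_labels=ann["is_driver_truth"].copy(),
                        causal_links=links)
    tables = {"recurrence": recurrence, "expression_outliers": expr,
              "splicing_outliers": spl, "activation_outliers": act,
              "splice_predictions": pred}
    return tables, truth


def simulate_validation_cohort(cfg: SimulationConfig):
    """Normalized-count-style matrix for the validation cohort caller.

    Log2-scale values are drawn from the stated two-component equal-variance
    Gaussian mixture (activated samples from the higher mean) and mapped to
    the count scale as 2^y - 1; membership is recorded in truth.
    """
    rng = np.random.default_rng(cfg.seed + 404)
    lo, hi = sorted(cfg.mixture_means)
    sample_ids, entities, member = [], [], []
    for entity, n in cfg.validation_entities.items():
        n_act = cfg.validation_n_activated.get(entity, 0)
        for i in range(n):
            sample_ids.append(f"{entity}_val_{i:02d}")
            entities.append(entity)
            member.append(1 if i < n_act else 0)
    member = np.array(member)
    y = rng.normal(np.where(member == 1, hi, lo), cfg.mixture_sd)
    counts = np.maximum(2.0 ** y - 1.0, 0.0)
    mat = pd.DataFrame({"sample_id": sample_ids, "entity": entities,
                        "normalized_count": counts})
    truth = GroundTruth(validation_membership=pd.Series(member, index=sample_ids))
    return mat, truth
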