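"""Readers, writers, and the core in-memory containers.

All tabular inputs are TSV with a header line and ``NA`` for missing values.
Genomic intervals are stored 0-based half-open internally; the TSV dialects
are documented 1-based inclusive and converted on read (BED-compatible
internals, VCF-compatible I/O).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("txcensus")

NA_REP = "NA"

# column contracts for the TSV dialects
COUNTS_INDEX = "gene_id"
GENE_COLUMNS = ["gene_id", "length_bp", "chrom", "start", "end", "tss", "strand",
                "is_driver_truth", "tissue_types", "roles"]
SAMPLE_COLUMNS = ["sample_id", "entity", "study_group", "lineage"]
SMALL_VARIANT_COLUMNS = ["sample_id", "gene_id", "position", "filter_status",
                         "gnomad_af", "vaf", "read_support", "consequences", "impact"]
SV_COLUMNS = ["sample_id", "gene_id", "filter_status", "paired_read_support",
              "gnomad_sv_exact_match", "entity_occurrence"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "call", "log_copy_ratio"]


class CensusIOError(ValueError):
    """Malformed input: missing column, duplicate ID, bad value."""


@dataclass
class CountsMatrix:
    """Gene x sample fragment (read-pair) counts with per-sample library sizes.

    ``library_size`` is the total number of mapped fragments per sample.  It
    may exceed the column sum (fragments mapping outside annotated genes) but
    must be positive.
    """

    counts: pd.DataFrame            # index: gene_id, columns: sample_id, int
    library_size: pd.Series         # index: sample_id, positive int

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CensusIOError(f"duplicate gene ID: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise CensusIOError(f"duplicate sample ID: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise CensusIOError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise CensusIOError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}")
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.library_size.isna().any():
            missing = self.library_size.index[self.library_size.isna()].tolist()
            raise CensusIOError(f"samples missing library size: {missing}")
        if (self.library_size <= 0).any():
            bad = self.library_size.index[self.library_size <= 0].tolist()
            raise CensusIOError(f"non-positive library size for samples: {bad}")
        self.library_size = self.library_size.astype(np.int64)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CensusIOError(f"{what}: missing column(s) {missing}")


def read_counts(counts_path: str | Path, library_size_path: str | Path | None = None,
                library_size_from: str = "supplied") -> CountsMatrix:
    """Read a gene x sample counts TSV (first column ``gene_id``).

    Library sizes come from a two-column TSV (sample_id, library_size) or, if
    ``library_size_from == "annotated"`` or no file is given, from the column
    sums over annotated genes.
    """
    df = pd.read_csv(counts_path, sep="\t", na_values=[NA_REP])
    _require_columns(df, [COUNTS_INDEX], "counts")
    df = df.set_index(COUNTS_INDEX)
    if df.isna().any().any():
        raise CensusIOError("counts: missing values not allowed")
    if library_size_from == "supplied" and library_size_path is not None:
        ls = pd.read_csv(library_size_path, sep="\t", na_values=[NA_REP])
        _require_columns(ls, ["sample_id", "library_size"], "library sizes")
        lib = ls.set_index("sample_id")["library_size"]
    else:
        lib = df.sum(axis=0)
    return CountsMatrix(counts=df, library_size=lib)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table; converts the 1-based inclusive
    ``start`` to 0-based half-open internally."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    _require_columns(df, GENE_COLUMNS, "gene annotation")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise CensusIOError(f"duplicate gene ID: {dup!r}")
    df = df.copy()
    df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
    validate_gene_annotation(df)
    return df.set_index("gene_id", drop=False)


def validate_gene_annotation(df: pd.DataFrame) -> None:
    if (df["length_bp"] < 1).any():
        bad = df.loc[df["length_bp"] < 1, "gene_id"].tolist()
        raise CensusIOError(f"genes with length_bp < 1: {bad}")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
        raise CensusIOError(f"genes with empty/inverted interval: {bad}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise CensusIOError(
            f"invalid strand for genes: {df.loc[bad_strand, 'gene_id'].tolist()}")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    _require_columns(df, SAMPLE_COLUMNS, "sample metadata")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CensusIOError(f"duplicate sample ID: {dup!r}")
    # every entity must map to exactly one study group
    groups = df.groupby("entity")["study_group"].nunique()
    if (groups > 1).any():
        raise CensusIOError(
            f"entities mapped to multiple study groups: {groups[groups > 1].index.tolist()}")
    bad = ~df["lineage"].isin(["myeloid", "lymphatic"])
    if bad.any():
        raise CensusIOError(
            f"unknown lineage tag for samples: {df.loc[bad, 'sample_id'].tolist()}")
    return df.set_index("sample_id", drop=False)


def read_table(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    _require_columns(df, required, what)
    return df


def load_inputs(paths: dict, config=None):
    """Load and cross-validate all pipeline inputs.

    ``paths`` maps logical names (counts, library_sizes, genes, samples,
    small_variants, structural_variants, segments, expression_outliers,
    splicing_outliers, splice_predictions, recurrence) to file paths; only
    counts, genes, and samples are mandatory.  Every sample referenced by the
    counts matrix or a variant/caller table must be present in the metadata
    and every referenced gene must be annotated; unresolved IDs raise with
    the offending identifiers listed.
    """
    from .config import DEFAULT_CONFIG
    config = config or DEFAULT_CONFIG
    genes = read_gene_annotation(paths["genes"])
    samples = read_sample_metadata(paths["samples"])
    counts = read_counts(paths["counts"], paths.get("library_sizes"),
                         library_size_from=config.library_size_from)

    loaded: dict[str, pd.DataFrame] = {}
    optional = {
        "small_variants": SMALL_VARIANT_COLUMNS,
        "structural_variants": SV_COLUMNS,
        "segments": SEGMENT_COLUMNS,
        "expression_outliers": ["gene_id", "sample_id", "p_value", "adjusted_p", "z_score"],
        "splicing_outliers": ["gene_id", "sample_id", "p_value", "adjusted_p", "delta_jaccard"],
        "splice_predictions": ["gene_id", "sample_id", "variant_id", "score"],
        "recurrence": ["gene_id", "tool", "score", "p_value", "q_value"],
    }
    for name, cols in optional.items():
        if name in paths and paths[name] is not None:
            loaded[name] = read_table(paths[name], cols, name)

    _check_cross_references(counts, genes, samples, loaded)
    logger.info("loaded %d genes x %d samples, %d auxiliary tables",
                len(counts.genes), len(counts.samples), len(loaded))
    return counts, genes, samples, loaded


def _check_cross_references(counts: CountsMatrix, genes: pd.DataFrame,
                            samples: pd.DataFrame, loaded: dict) -> None:
    orphans = counts.samples.difference(samples.index)
    if len(orphans):
        raise CensusIOError(f"counts samples absent from metadata: {sorted(orphans)}")
    unannotated = counts.genes.difference(genes.index)
    if len(unannotated):
        raise CensusIOError(f"counts genes missing annotation: {sorted(unannotated)}")
    for name, df in loaded.items():
        if "sample_id" in df.columns:
            orphan = set(df["sample_id"]) - set(samples.index)
            if orphan:
                raise CensusIOError(f"{name}: samples absent from metadata: {sorted(orphan)}")
        if "gene_id" in df.columns:
            orphan = set(df["gene_id"]) - set(genes.index)
            if orphan:
                raise CensusIOError(f"{name}: genes missing annotation: {sorted(orphan)}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def write_census(calls: pd.DataFrame, meta: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write the aggregated census: one gene x entity count TSV per category.

    ``calls`` is an aberration-call table (gene_id, sample_id, category, ...);
    counts are numbers of distinct called samples per gene and entity.
    Output is byte-stable: rows sorted by gene, columns by entity.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entity = meta["entity"]
    written: list[Path] = []
    categories = sorted(calls["category"].unique()) if len(calls) else []
    for cat in categories:
        sub = calls.loc[calls["category"] == cat, ["gene_id", "sample_id"]].drop_duplicates()
        sub = sub.assign(entity=sub["sample_id"].map(entity))
        table = (sub.groupby(["gene_id", "entity"]).size().unstack(fill_value=0)
                 .sort_index())
        table = table.reindex(sorted(table.columns), axis=1)
        path = out_dir / f"census_{cat}.tsv"
        table.reset_index().to_csv(path, sep="\t", index=False, na_rep=NA_REP)
        written.append(path)
    if not categories:
        path = out_dir / "census_empty.tsv"
        pd.DataFrame(columns=["gene_id"]).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
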