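"""Reading, filtering and assembly of longitudinal microbiome datasets.

A study is a sample × taxon abundance table (counts or relative abundances)
plus per-sample metadata: which subject the sample came from, when it was
taken, optionally a pre-assigned community state, and the values of one or
more external perturbations (diet, drugs, behaviour). This module reads the
two tables, applies the standard longitudinal preprocessing (drop low-depth
samples, drop empty taxa, renormalise), and joins them into a
:class:`LongitudinalDataset` ordered by subject and time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("micromdp")

#: Column names required in every metadata table.
REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "time_point")

#: Row-sum agreement tolerance for relative-abundance tables.
RELATIVE_SUM_TOL = 1e-6


class FormatError(ValueError):
    """An input file violates its declared format."""


@dataclass
class AbundanceMatrix:
    """Sample × taxon abundance table.

    Parameters
    ----------
    data
        DataFrame with one row per sample (index = sample ids) and one
        column per taxon (columns = taxon ids); values are non-negative.
    units_mode
        ``"counts"`` for raw read counts, ``"relative"`` for rows that have
        been rescaled to a common total (100 or 1).
    """

    data: pd.DataFrame
    units_mode: Literal["counts", "relative"] = "counts"
    relative_total: float = 100.0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated taxon ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if self.units_mode == "relative" and len(self.data):
            sums = values.sum(axis=1)
            bad = np.abs(sums - self.relative_total) > RELATIVE_SUM_TOL * max(1.0, self.relative_total)
            if bad.any():
                which = self.data.index[bad][:5].tolist()
                raise FormatError(
                    f"relative-abundance rows do not sum to {self.relative_total}: {which}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy(dtype=float)


@dataclass
class LongitudinalDataset:
    """Joined abundance + metadata, ordered by (subject, time).

    ``metadata`` has columns ``sample_id, subject_id, time_point`` plus any
    state-label and perturbation columns; it is sorted by subject then time.
    Subjects with a single sample are retained but contribute no transitions.
    """

    abundance: AbundanceMatrix
    metadata: pd.DataFrame
    perturbation_schemas: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_METADATA_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing required columns: {sorted(missing)}")
        meta_ids = set(self.metadata["sample_id"])
        ab_ids = set(self.abundance.sample_ids)
        if meta_ids != ab_ids:
            raise ValueError(
                "abundance and metadata disagree on sample ids; "
                "use assemble_dataset to inner-join them"
            )
        dup = self.metadata["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicated sample ids in metadata: {self.metadata.loc[dup, 'sample_id'].tolist()}"
            )
        collisions = self.metadata.duplicated(subset=["subject_id", "time_point"], keep=False)
        if collisions.any():
            pairs = (
                self.metadata.loc[collisions, ["subject_id", "time_point"]]
                .drop_duplicates()
                .to_records(index=False)
                .tolist()
            )
            raise ValueError(f"duplicate (subject, time) pairs: {pairs}")

    @property
    def subjects(self) -> list:
        return list(self.metadata["subject_id"].unique())

    def subject_samples(self, subject_id) -> pd.DataFrame:
        """Samples of one subject, sorted by time (strictly increasing)."""
        rows = self.metadata[self.metadata["subject_id"] == subject_id]
        return rows.sort_values("time_point")

    @property
    def n_samples(self) -> int:
        return len(self.metadata)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    format: Literal["tsv", "biom"] = "tsv",
    orientation: Literal["auto", "taxa_rows", "samples_rows"] = "auto",
    units_mode: Literal["counts", "relative"] = "counts",
    relative_total: float = 100.0,
) -> AbundanceMatrix:
    """Read an abundance table from TSV or BIOM 2.x.

    TSV layout is taxa-as-rows (first column taxon id, header = sample ids,
    the common OTU-table convention) or samples-as-rows; ``orientation="auto"``
    keeps taxa-as-rows unless the first header cell names a sample-id column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "biom":
        df = _read_biom_hdf5(path)
    elif format == "tsv":
        df = _read_tsv(path, orientation)
    else:
        raise ValueError(f"unknown format {format!r}")
    return AbundanceMatrix(df, units_mode=units_mode, relative_total=relative_total)


def _read_tsv(path: Path, orientation: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if raw.empty and raw.shape[1] == 0:
        raise FormatError(f"{path}: empty table")
    for col in raw.columns:
        cleaned = pd.to_numeric(raw[col], errors="coerce")
        if cleaned.isna().any():
            row = raw.index[cleaned.isna()][0]
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r} "
                f"(value {raw.loc[row, col]!r})"
            )
        if (cleaned < 0).any():
            row = raw.index[cleaned < 0][0]
            raise FormatError(
                f"{path}: negative value at row {row!r}, column {col!r} "
                f"(value {raw.loc[row, col]!r})"
            )
        raw[col] = cleaned
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    first_header = str(raw.index.name or "").strip().lower()
    if orientation == "samples_rows" or (
        orientation == "auto" and first_header in {"sample_id", "sample", "#sampleid"}
    ):
        return raw
    # taxa-as-rows: transpose so rows become samples
    return raw.T


def _read_biom_hdf5(path: Path) -> pd.DataFrame:
    """Read a BIOM 2.x HDF5 table (observations = taxa, samples = columns)."""
    import h5py
    from scipy import sparse

    try:
        with h5py.File(path, "r") as fh:
            taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in fh["observation/ids"][:]]
            samples = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
            grp = fh["observation/matrix"]
            mat = sparse.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(taxa), len(samples)),
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot parse {path} as BIOM 2.x HDF5: {exc}") from exc
    dense = np.asarray(mat.todense(), dtype=float)
    return pd.DataFrame(dense.T, index=pd.Index(samples), columns=taxa)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a TSV abundance table (taxa rows × sample columns)."""
    out = matrix.data.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV with the required identifier columns."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = set(REQUIRED_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    meta["sample_id"] = meta["sample_id"].str.strip()
    return meta


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    matrix: AbundanceMatrix,
    min_reads: int = 10_000,
    drop_zero_taxa: bool = True,
    normalize: Literal["none", "proportion", "percent"] = "none",
    exclude_samples: Sequence[str] = (),
) -> AbundanceMatrix:
    """Longitudinal preprocessing of an abundance table.

    Removes samples with total reads strictly below ``min_reads`` (a sample
    with exactly ``min_reads`` reads is kept), removes taxa whose total
    abundance is zero, and optionally rescales each row to proportions
    (sum 1) or percentages (sum 100). Study-specific removals (other body
    sites, contaminated runs, ...) are passed as an explicit
    ``exclude_samples`` list rather than hard-coded.

    The operation is idempotent and never increases either dimension.
    """
    df = matrix.data
    if exclude_samples:
        df = df.drop(index=[s for s in exclude_samples if s in df.index])
    if min_reads and min_reads > 0:
        if matrix.units_mode != "counts":
            raise ValueError("min_reads filtering requires a counts-mode matrix")
        totals = df.sum(axis=1)
        kept = totals >= min_reads
        n_drop = int((~kept).sum())
        if n_drop:
            logger.info("preprocess: dropped %d samples with < %d reads", n_drop, min_reads)
        df = df.loc[kept]
    if df.shape[0] == 0:
        raise ValueError("preprocess removed every sample (empty dataset)")
    if drop_zero_taxa:
        col_sums = df.sum(axis=0)
        df = df.loc[:, col_sums > 0]
    units = matrix.units_mode
    total = matrix.relative_total
    if normalize != "none":
        row_sums = df.sum(axis=1)
        if (row_sums == 0).any():
            zeros = df.index[row_sums == 0].tolist()
            raise ValueError(f"cannot normalize all-zero rows: {zeros}")
        target = 100.0 if normalize == "percent" else 1.0
        already = units == "relative" and total == target
        if not already:
            df = df.div(row_sums, axis=0) * target
        units, total = "relative", target
    return AbundanceMatrix(df, units_mode=units, relative_total=total)


def dominant_taxa_filter(
    matrix: AbundanceMatrix,
    threshold: float = 0.01,
    keep: Literal["dominant", "non_dominant"] = "dominant",
) -> AbundanceMatrix:
    """Restrict to dominant (or non-dominant) taxa.

    Dominant taxa are those whose mean relative abundance across samples is
    at least ``threshold`` (a fraction, e.g. 0.01 for 1%); the complement is
    the non-dominant set. The cut is on abundance, not rank.
    """
    props = matrix.data.div(matrix.data.sum(axis=1), axis=0)
    mean_prop = props.mean(axis=0)
    dominant = mean_prop >= threshold
    mask = dominant if keep == "dominant" else ~dominant
    if not mask.any():
        raise ValueError(f"no taxa left after {keep} filter at threshold {threshold}")
    return replace(matrix, data=matrix.data.loc[:, mask])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    schemas: Sequence = (),
) -> LongitudinalDataset:
    """Inner-join abundances with metadata into a LongitudinalDataset.

    Samples present on only one side are dropped (and logged). Within each
    subject, time points must be unique; the dataset is sorted by subject
    then time.
    """
    missing = set(REQUIRED_METADATA_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    shared = [s for s in meta["sample_id"] if s in set(matrix.sample_ids)]
    if not shared:
        raise ValueError("no sample-id overlap between abundance and metadata")
    dropped_meta = sorted(set(meta["sample_id"]) - set(shared))
    dropped_ab = sorted(set(matrix.sample_ids) - set(shared))
    if dropped_meta:
        logger.info("assemble_dataset: %d metadata rows lack abundances: %s", len(dropped_meta), dropped_meta)
    if dropped_ab:
        logger.info("assemble_dataset: %d abundance rows lack metadata: %s", len(dropped_ab), dropped_ab)
    meta = meta[meta["sample_id"].isin(shared)]
    meta = meta.sort_values(["subject_id", "time_point"], kind="stable").reset_index(drop=True)
    sub = replace(matrix, data=matrix.data.loc[meta["sample_id"].tolist()])
    return LongitudinalDataset(sub, meta, list(schemas))
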