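"""Readers and writers for the flat-file artifacts of the pipeline.

All external formats are plain text: tab-delimited expression matrices
(features in rows, strains in columns), a strain lifespan table, a
two-column feature-to-gene map, GMT gene-set collections, and TSV result
tables.  Missing expression values are encoded as empty cells or ``NA`` on
read and written back as empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "combined")
OMICS_TYPES = ("transcript", "protein")
NORMALIZATIONS = ("zscore", "two_z_plus_8", "other")

#: strings treated as missing values on read
NA_VALUES = ["", "NA"]


class ParseError(ValueError):
    """A flat file violated the expected dialect."""


@dataclass
class OmicsDataset:
    """One tissue/sex/omics-type expression matrix.

    ``values`` is a features x strains DataFrame of floats; NaN marks a
    missing measurement.  ``normalization`` declares the scale convention of
    the stored numbers: ``zscore`` (mean 0, SD 1), ``two_z_plus_8``
    (z-scores rescaled to mean 8, SD 2 — a GeneNetwork export dialect), or
    ``other``.
    """

    dataset_id: str
    tissue: str
    sex: str
    omics_type: str
    normalization: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.omics_type not in OMICS_TYPES:
            raise ValueError(
                f"omics_type must be one of {OMICS_TYPES}, got {self.omics_type!r}"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate strain ids: {dups}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_zscore(self) -> "OmicsDataset":
        """Return the dataset on the z-score scale.

        ``two_z_plus_8`` values are mapped through ``(x - 8) / 2``;
        ``zscore`` and ``other`` values are passed through unchanged (for
        ``other`` the caller is responsible for the convention).
        """
        if self.normalization == "two_z_plus_8":
            return replace(
                self, values=from_two_z_plus_8(self.values), normalization="zscore"
            )
        return self


def from_two_z_plus_8(values):
    """Convert a matrix from the 2z+8 convention (mean 8, SD 2) to z-scores."""
    return (values - 8.0) / 2.0


def to_two_z_plus_8(values):
    """Rescale z-scores to the 2z+8 convention (mean 8, SD 2)."""
    return 2.0 * values + 8.0


def read_expression_matrix(
    path,
    *,
    dataset_id: str,
    tissue: str = "",
    sex: str = "combined",
    omics_type: str = "transcript",
    normalization: str = "zscore",
    transpose: bool = False,
) -> OmicsDataset:
    """Read a tab-delimited expression matrix.

    First column holds feature ids, the header row holds strain ids; empty
    cells and ``NA`` are missing.  ``transpose=True`` accepts the
    strains-in-rows dialect.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ids = header[1:]
    if len(set(ids)) != len(ids):  # pandas would silently mangle duplicates
        dup = next(i for n, i in enumerate(ids) if i in ids[:n])
        raise ParseError(f"{path}: duplicate column id {dup!r} in header")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=NA_VALUES, keep_default_na=False,
    )
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    values = pd.DataFrame(numeric, index=raw.index)
    if transpose:
        values = values.T
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    return OmicsDataset(
        dataset_id=dataset_id, tissue=tissue, sex=sex,
        omics_type=omics_type, normalization=normalization, values=values,
    )


def write_expression_matrix(dataset: OmicsDataset, path) -> None:
    """Write the matrix back in the canonical TSV dialect (missing -> empty)."""
    out = dataset.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_lifespan_table(path) -> pd.DataFrame:
    """Read a strain lifespan TSV: strain_id, median_lifespan_days, sex."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "sex": str})
    required = {"strain_id", "median_lifespan_days", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: lifespan table missing columns {sorted(missing)}")
    return validate_lifespan_table(df)


def validate_lifespan_table(df: pd.DataFrame) -> pd.DataFrame:
    if df["median_lifespan_days"].le(0).any() or df["median_lifespan_days"].isna().any():
        raise ValueError("median lifespans must be strictly positive")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)}")
    if df.duplicated(subset=["strain_id", "sex"]).any():
        dups = df.loc[df.duplicated(subset=["strain_id", "sex"]), "strain_id"].tolist()
        raise ValueError(f"duplicate (strain_id, sex) entries: {dups}")
    return df.reset_index(drop=True)


def write_lifespan_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_gene_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping feature_id -> gene_id (many-to-one)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: feature map needs two columns")
    feat, gene = df.columns[:2]
    mapping = {}
    for f, g in zip(df[feat], df[gene]):
        if not isinstance(f, str) or not f.strip():
            raise ParseError(f"{path}: empty feature id in map")
        mapping[f.strip()] = str(g).strip()
    return mapping


def write_feature_gene_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"feature_id": list(mapping), "gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def write_score_table(table, path) -> None:
    """Write a longevity score table as TSV (feature/gene, r, slope, ...)."""
    out = table.scores.copy()
    out.index.name = f"{table.key}_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_score_table(path, *, dataset_id: str, thresholds=(0.4, 0.7)):
    """Read a score-table TSV back into a ``ScoreTable``."""
    from .scoring import ScoreTable  # local import: io stays scoring-free

    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=NA_VALUES, keep_default_na=False)
    if "r" not in df.columns:
        raise ParseError(f"{path}: score table lacks an 'r' column")
    df["r"] = pd.to_numeric(df["r"], errors="raise")
    if "slope" in df.columns:
        df["slope"] = pd.to_numeric(df["slope"], errors="raise")
    if "n_used" in df.columns:
        df["n_used"] = pd.to_numeric(df["n_used"], errors="raise").astype(int)
    for col in df.columns:
        if col.startswith("pass_"):
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    key = "gene" if (df.index.name or "").startswith("gene") else "feature"
    df.index = df.index.astype(str)
    df.index.name = None
    return ScoreTable(dataset_id=dataset_id, scores=df,
                      thresholds=tuple(sorted(thresholds)), key=key)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    set_name: str
    members: frozenset


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (the GMT content)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sets:
            if s.set_id in seen:
                raise ParseError(f"duplicate gene-set id {s.set_id!r}")
            if not s.members:
                raise ParseError(f"gene set {s.set_id!r} has no members")
            seen.add(s.set_id)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def all_members(self) -> set:
        out: set = set()
        for s in self.sets:
            out |= s.members
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-delimited lines of id, description, members..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            # trailing empty member fields are tolerated
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            set_id, name, *members = fields
            sets.append(
                GeneSet(set_id=set_id, set_name=name,
                        members=frozenset(m.strip() for m in members if m.strip()))
            )
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.set_name, *sorted(s.members)]) + "\n")
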