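"""Data containers and tab-separated I/O for the RIP-seq pipeline.

Every stage of the pipeline consumes and produces plain TSV text (plus a
GMT-dialect gene-set file).  Four containers are defined here:

* :class:`CountMatrix` — nonnegative integer gene x sample counts,
* :class:`SampleSheet` — the paired IP/Total design (bait, replicate, fraction),
* :class:`GeneSetCollection` — term -> member-gene mapping,
* :class:`CovariateTable` — per-gene numeric covariates with missing values.

Gene and sample identifiers are opaque strings throughout; there is no
coordinate or strand semantics anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRACTION_IP = "IP"
FRACTION_TOTAL = "Total"


class ParseError(ValueError):
    """A cell or line in an input file could not be interpreted."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


class DesignError(ValidationError):
    """The sample sheet does not describe a valid paired IP/Total design."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Invariants (checked at construction): unique gene and sample ids, all
    counts integral and >= 0, and every library (column) sum > 0.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if (values < 0).any():
            gene, sample = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[gene]!r}, sample {df.columns[sample]!r}"
            )
        lib = values.sum(axis=0)
        if (lib <= 0).any():
            bad = df.columns[lib <= 0].tolist()
            raise ValidationError(f"zero library size for samples: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (header = sample ids, col 0 = gene ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        gene, sample = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric count at gene {raw.index[gene]!r}, "
            f"sample {raw.columns[sample]!r} (value {raw.iat[gene, sample]!r})"
        )
    values = numeric.to_numpy()
    if not np.allclose(values, np.round(values)):
        gene, sample = np.argwhere(values != np.round(values))[0]
        raise ParseError(
            f"{path}: non-integer count at gene {numeric.index[gene]!r}, "
            f"sample {numeric.columns[sample]!r}"
        )
    if (values < 0).any():
        gene, sample = np.argwhere(values < 0)[0]
        raise ParseError(
            f"{path}: negative count at gene {numeric.index[gene]!r}, "
            f"sample {numeric.columns[sample]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    return CountMatrix(numeric.astype(np.int64))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "protein", "replicate", "fraction"]


@dataclass(frozen=True)
class SampleSheet:
    """Paired IP/Total design: one IP and one Total library per (bait, replicate)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, _SHEET_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["protein"] = df["protein"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        frac = df["fraction"].astype(str).str.strip().str.lower()
        mapped = frac.map({"ip": FRACTION_IP, "total": FRACTION_TOTAL})
        if mapped.isna().any():
            bad = df.loc[mapped.isna(), "fraction"].unique().tolist()
            raise ParseError(f"unknown fraction value(s): {bad} (expected IP or Total)")
        df["fraction"] = mapped
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        # exactly one IP and one Total per (protein, replicate)
        for (protein, rep), grp in df.groupby(["protein", "replicate"]):
            fracs = sorted(grp["fraction"].tolist())
            if fracs != [FRACTION_IP, FRACTION_TOTAL]:
                raise DesignError(
                    f"(protein={protein!r}, replicate={rep}) must have exactly one IP "
                    f"and one Total sample, found {fracs}"
                )
        for protein, grp in df.groupby("protein"):
            n_rep = grp["replicate"].nunique()
            if n_rep < 2:
                raise DesignError(
                    f"protein {protein!r} has {n_rep} replicate(s); at least 2 required"
                )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.table["protein"]))

    def replicates(self, protein: str) -> list[int]:
        sub = self.table[self.table["protein"] == protein]
        return sorted(sub["replicate"].unique())

    def samples(self, protein: str, fraction: str | None = None) -> list[str]:
        sub = self.table[self.table["protein"] == protein]
        if fraction is not None:
            sub = sub[sub["fraction"] == fraction]
        return sub.sort_values(["replicate", "fraction"])["sample_id"].tolist()

    def sample_id(self, protein: str, replicate: int, fraction: str) -> str:
        sub = self.table[
            (self.table["protein"] == protein)
            & (self.table["replicate"] == replicate)
            & (self.table["fraction"] == fraction)
        ]
        if len(sub) != 1:
            raise KeyError((protein, replicate, fraction))
        return sub["sample_id"].iloc[0]

    def validate_against(self, matrix: CountMatrix) -> None:
        """Require the sheet's sample ids and the matrix's columns to be the
        same set (order is never significant)."""
        sheet_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if sheet_ids != matrix_ids:
            only_sheet = sorted(sheet_ids - matrix_ids)
            only_matrix = sorted(matrix_ids - sheet_ids)
            raise ValidationError(
                f"sample sheet and count matrix disagree: only in sheet {only_sheet[:5]}, "
                f"only in matrix {only_matrix[:5]}"
            )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in df.columns:
        try:
            df["replicate"] = df["replicate"].astype(int)
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer replicate value ({exc})") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT dialect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """term_id -> (term_name, frozenset of member gene ids)."""

    terms: Mapping[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (name, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {term_id!r} has no members")

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``term_id TAB term_name TAB member1 TAB member2 ...``.

    Duplicated members within a term are collapsed; terms with an empty member
    list are skipped with a logged warning.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least term_id and name")
            term_id, term_name = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                logger.warning("%s:%d: term %r has no members; skipped", path, lineno, term_id)
                continue
            if term_id in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (term_name, members)
    return GeneSetCollection(terms)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term_id in sorted(collection.terms):
            name, members = collection.terms[term_id]
            handle.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# CovariateTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTable:
    """Per-gene numeric covariates (missing values allowed, stored as NaN)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene ids in covariate table")
        for col in df.columns:
            if not df[col].notna().any():
                raise ValidationError(f"covariate {col!r} has no non-missing values")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"covariate {name!r} not present (have {self.covariate_names})")
        return self.values[name]


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df = df.apply(pd.to_numeric, errors="coerce")
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    df = table.values.sort_index()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any result table as TSV with a header (generic stage output)."""
    df.to_csv(path, sep="\t", index=index)
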