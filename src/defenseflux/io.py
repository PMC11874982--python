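"""Pangenome data model and readers/writers for the standard flat formats.

Supported formats: Roary ``Rtab`` and ``gene_presence_absence.csv`` dialects
for the presence/absence matrix, and TSV for trait tables, family annotations
and all result tables.  Floats in result tables are serialised at 10
significant digits; all writers round-trip through their readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import StrainTree

log = logging.getLogger("defenseflux")

DEFENSE_SYSTEMS = ("RM", "DMS", "Abi", "CRISPR", "Gabija", "DRT", "CBASS")
MGE_CLASSES = ("prophage", "plasmid", "transposon")
FAMILY_CLASSES = MGE_CLASSES + ("none",)

#: leading metadata columns of Roary's gene_presence_absence.csv
_ROARY_META_COLS = 14


class DataError(ValueError):
    """Raised for malformed or inconsistent tabular inputs."""


@dataclass
class PresenceMatrix:
    """Binary genomes x gene-families matrix (1 = family present)."""

    df: pd.DataFrame  # index: genome_ids, columns: family_ids, values 0/1

    def __post_init__(self):
        vals = self.df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataError("presence matrix entries must be 0/1")
        if self.df.columns.duplicated().any():
            raise DataError("duplicated family id in presence matrix")
        if self.df.index.duplicated().any():
            raise DataError("duplicated genome id in presence matrix")
        self.df = self.df.astype(np.int8)

    @property
    def genome_ids(self) -> list:
        return list(self.df.index)

    @property
    def family_ids(self) -> list:
        return list(self.df.columns)

    def singleton_flags(self) -> pd.Series:
        """Families present in exactly one genome."""
        return self.df.sum(axis=0).eq(1).rename("singleton")

    def aligned_to(self, tree: StrainTree) -> "PresenceMatrix":
        """Reorder rows to the tree's leaf order; genome sets must match."""
        leaves = tree.leaf_labels
        if set(leaves) != set(self.genome_ids):
            missing = set(leaves) ^ set(self.genome_ids)
            raise DataError(
                f"genome set does not match tree leaves (symmetric "
                f"difference: {sorted(missing)[:5]}...)"
            )
        return PresenceMatrix(self.df.loc[leaves])

    def __eq__(self, other):
        return isinstance(other, PresenceMatrix) and self.df.sort_index(
            axis=0
        ).sort_index(axis=1).equals(other.df.sort_index(axis=0).sort_index(axis=1))


@dataclass
class FamilyAnnotation:
    """Per-family class labels: MGE class, COG letter, defense system,
    MGE-residency and singleton flags."""

    df: pd.DataFrame  # index family_id; columns mge_class, cog_category,
    # defense_system, mge_resident, singleton

    COLUMNS = ("mge_class", "cog_category", "defense_system", "mge_resident", "singleton")

    def __post_init__(self):
        for col in self.COLUMNS:
            if col not in self.df.columns:
                raise DataError(f"annotation missing column {col!r}")
        bad = set(self.df["mge_class"]) - set(FAMILY_CLASSES)
        if bad:
            raise DataError(f"unknown mge_class values {sorted(bad)}")
        bad = set(self.df["defense_system"]) - set(DEFENSE_SYSTEMS) - {"none"}
        if bad:
            raise DataError(
                f"unknown defense_system values {sorted(bad)}; accepted: "
                f"{list(DEFENSE_SYSTEMS) + ['none']}"
            )
        if self.df.index.duplicated().any():
            raise DataError("duplicated family id in annotation")
        self.df = self.df.astype(
            {"mge_resident": bool, "singleton": bool}
        )

    @property
    def family_ids(self) -> list:
        return list(self.df.index)

    def check_consistent(self, matrix: PresenceMatrix) -> None:
        if set(self.family_ids) != set(matrix.family_ids):
            raise DataError("annotation families do not match presence matrix")
        flags = matrix.singleton_flags()
        if not self.df["singleton"].reindex(flags.index).eq(flags).all():
            raise DataError("singleton flags inconsistent with column sums")

    def __eq__(self, other):
        return isinstance(other, FamilyAnnotation) and self.df.sort_index().equals(
            other.df.sort_index()
        )


@dataclass
class TraitTable:
    """Genome x defense-system presence (0/1)."""

    df: pd.DataFrame  # index genome_id; columns: defense systems

    def __post_init__(self):
        bad = set(self.df.columns) - set(DEFENSE_SYSTEMS)
        if bad:
            raise DataError(
                f"unknown defense system(s) {sorted(bad)}; accepted names: "
                f"{list(DEFENSE_SYSTEMS)}"
            )
        if not np.isin(self.df.to_numpy(), (0, 1)).all():
            raise DataError("trait table entries must be 0/1")
        self.df = self.df.astype(np.int8)

    @property
    def genome_ids(self) -> list:
        return list(self.df.index)

    @property
    def systems(self) -> list:
        return list(self.df.columns)

    def aligned_to(self, tree: StrainTree) -> "TraitTable":
        leaves = tree.leaf_labels
        if set(leaves) != set(self.genome_ids):
            raise DataError("trait table genomes do not match tree leaves")
        return TraitTable(self.df.loc[leaves])

    def __eq__(self, other):
        return isinstance(other, TraitTable) and self.df.sort_index(axis=0).sort_index(
            axis=1
        ).equals(other.df.sort_index(axis=0).sort_index(axis=1))


# --------------------------------------------------------------------- readers

def read_presence_matrix(path, dialect: str = "rtab"):
    """Read a Roary-style presence/absence matrix.

    Parameters
    ----------
    dialect : ``"rtab"`` (tab-separated 0/1, families in rows) or
        ``"roary_csv"`` (gene_presence_absence.csv; presence = non-empty cell).

    Returns
    -------
    (PresenceMatrix, pandas.Series)
        The matrix (genomes x families) and the derived singleton flags.
    """
    if dialect == "rtab":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        vals = raw.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataError("non-binary cell in Rtab matrix")
        if raw.index.duplicated().any():
            raise DataError("duplicated family id in Rtab matrix")
        matrix = PresenceMatrix(raw.T)
    elif dialect == "roary_csv":
        raw = pd.read_csv(path, index_col=0, dtype=str)
        if raw.shape[1] < _ROARY_META_COLS:
            raise DataError("roary_csv with too few columns")
        genomes = raw.columns[_ROARY_META_COLS - 1:]
        present = raw[genomes].notna() & raw[genomes].ne("")
        matrix = PresenceMatrix(present.astype(int).T)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    log.info("read_presence_matrix path=%s dialect=%s genomes=%d families=%d",
             path, dialect, len(matrix.genome_ids), len(matrix.family_ids))
    return matrix, matrix.singleton_flags()


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TraitTable(df)


def write_trait_table(table: TraitTable, path) -> None:
    out = table.df.copy()
    out.index.name = "genome"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> FamilyAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    df["mge_resident"] = df["mge_resident"].astype(str).str.lower().isin(("true", "1"))
    df["singleton"] = df["singleton"].astype(str).str.lower().isin(("true", "1"))
    return FamilyAnnotation(df)


def write_annotation(annot: FamilyAnnotation, path) -> None:
    out = annot.df[list(FamilyAnnotation.COLUMNS)].copy()
    out.index.name = "family"
    out.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV, floats at 10 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
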