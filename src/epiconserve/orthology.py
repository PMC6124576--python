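"""Cross-species orthologue tables and re-keying of matrices onto groups.

A table row maps one orthologue group id to one gene id per species, with an
optional copy count per species.  The 1:1:1 subset (copy count exactly one in
every species) defines the comparison universe for all downstream overlap
statistics.  Genes a matrix does not quantify are carried as NaN, never as
zero — zero-imputation would fabricate downregulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidationError
from .expression import ExpressionMatrix

GROUP_COLUMN = "group_id"


@dataclass
class OrthologTable:
    """Orthologue groups with one gene column (and copy count) per species.

    ``table`` columns: ``group_id``, ``<species>_gene`` per species, and
    ``<species>_count`` per species (defaulting to 1 when absent from the
    input file).
    """

    table: pd.DataFrame
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        t = self.table
        if t[GROUP_COLUMN].duplicated().any():
            dup = t.loc[t[GROUP_COLUMN].duplicated(), GROUP_COLUMN].tolist()
            raise ValidationError(f"duplicate group ids: {dup[:10]}")
        for sp in self.species:
            col = f"{sp}_gene"
            if col not in t.columns:
                raise DataFormatError(f"missing species column {col!r}")
            genes = t[col].dropna()
            if genes.duplicated().any():
                dup = sorted(genes[genes.duplicated()].unique().tolist())
                raise ValidationError(
                    f"gene id(s) present in more than one group for "
                    f"species {sp!r}: {dup[:10]}"
                )
            cnt = f"{sp}_count"
            if cnt not in t.columns:
                t = t.assign(**{cnt: 1})
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def group_ids(self) -> pd.Index:
        return pd.Index(self.table[GROUP_COLUMN])

    def gene_map(self, species: str) -> pd.Series:
        """group_id -> gene_id for one species."""
        if species not in self.species:
            raise ValidationError(f"unknown species {species!r}")
        return self.table.set_index(GROUP_COLUMN)[f"{species}_gene"]


def load_ortholog_table(path, species: Sequence[str]) -> OrthologTable:
    """Load and validate an orthologue TSV.

    Expected columns: ``group_id``, one ``<species>_gene`` per species, and
    optional ``<species>_count`` columns.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"malformed orthologue table {path}: {exc}") from exc
    if GROUP_COLUMN not in df.columns:
        raise DataFormatError(f"orthologue table lacks a {GROUP_COLUMN!r} column")
    for sp in species:
        cnt = f"{sp}_count"
        if cnt in df.columns:
            df[cnt] = pd.to_numeric(df[cnt], errors="raise").astype(int)
    return OrthologTable(df, tuple(species))


def filter_one_to_one(table: OrthologTable) -> OrthologTable:
    """Keep groups with copy count exactly 1 in every species; order kept."""
    mask = pd.Series(True, index=table.table.index)
    for sp in table.species:
        cnt = table.table[f"{sp}_count"]
        gene = table.table[f"{sp}_gene"]
        mask &= (cnt == 1) & gene.notna()
    return OrthologTable(table.table.loc[mask].reset_index(drop=True), table.species)


def map_to_groups(matrix: ExpressionMatrix, table: OrthologTable,
                  species: str) -> ExpressionMatrix:
    """Re-key a species matrix from gene ids onto 1:1:1 orthologue group ids.

    The output has one row per 1:1:1 group, in table order.  Groups whose
    gene is absent from the matrix get NaN (missing), not zero.
    """
    one = filter_one_to_one(table)
    gmap = one.gene_map(species)
    reindexed = matrix.data.reindex(gmap.values)
    reindexed.index = gmap.index
    if reindexed.notna().any(axis=1).sum() == 0:
        raise ValidationError(
            f"no orthologues matched between matrix and table for {species!r}"
        )
    return ExpressionMatrix(reindexed, matrix.samples, matrix.unit)


def shared_universe(matrices: dict[str, ExpressionMatrix]) -> list[str]:
    """Group ids quantified (non-missing in every sample) in every species.

    This complete-case 1:1:1 universe is the N used by all overlap
    statistics.
    """
    keep: pd.Series | None = None
    for mat in matrices.values():
        ok = mat.data.notna().all(axis=1)
        keep = ok if keep is None else (keep & ok.reindex(keep.index, fill_value=False))
    if keep is None:
        raise ValidationError("no matrices given")
    return list(keep.index[keep])
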