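"""Expression matrices, normalisation, expressed-gene calling and Venn overlaps.

The central container is :class:`ExpressionMatrix`: a genes-by-samples table of
nonnegative values plus a sample sheet (species, stage or culture condition,
replicate) and a unit tag recording the transform history (``raw`` counts,
``cpm``, or ``log2cpm``).  Values may be NaN for orthologue groups that a
species' matrix does not quantify; missingness is propagated, never imputed
as zero.

"Expressed" calls use a threshold rule (at least ``min_level`` normalised
units in at least ``min_fraction`` of a group's samples); the rule is
deliberately explicit and configurable because published expressed-gene
counts rarely come with a reusable definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

SAMPLE_SHEET_COLUMNS = ("species", "stage_or_condition", "replicate")

VALID_UNITS = ("raw", "cpm", "log2cpm")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by gene (or orthologue-group) id, one column per
        sample.  Values are nonnegative reals; NaN marks genes not quantified.
    samples:
        DataFrame indexed by sample id with columns ``species``,
        ``stage_or_condition`` and ``replicate``.  Index must equal the data
        columns (same order).
    unit:
        One of ``raw``, ``cpm``, ``log2cpm``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "raw"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ConfigurationError(
                f"unit must be one of {VALID_UNITS}, got {self.unit!r}"
            )
        if list(self.data.columns) != list(self.samples.index):
            raise ValidationError("sample sheet index must match matrix columns")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if self.samples[list(SAMPLE_SHEET_COLUMNS)].isna().any().any():
            bad = self.samples.index[
                self.samples[list(SAMPLE_SHEET_COLUMNS)].isna().any(axis=1)
            ].tolist()
            raise ValidationError(f"samples with incomplete metadata: {bad}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("expression values must be nonnegative")

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def select_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.data[ids], self.samples.loc[ids], self.unit)

    def group_samples(self, species: str | None = None,
                      stage_or_condition: str | None = None) -> list[str]:
        """Sample ids matching the given species and/or stage/condition."""
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if stage_or_condition is not None:
            mask &= self.samples["stage_or_condition"] == stage_or_condition
        return list(self.samples.index[mask])

    def complete_cases(self) -> "ExpressionMatrix":
        """Drop genes with any missing value (complete-case restriction)."""
        keep = self.data.notna().all(axis=1)
        return ExpressionMatrix(self.data.loc[keep], self.samples, self.unit)


@dataclass
class ExpressedSets:
    """Expressed-gene sets per (species, stage), with the rule that made them."""

    sets: dict[tuple[str, str], set[str]]
    min_level: float
    min_fraction: float
    universe: set[str] = field(default_factory=set)


def normalize(matrix: ExpressionMatrix, method: str = "cpm",
              log2_offset: float | None = None) -> ExpressionMatrix:
    """Normalise a raw-count matrix to counts-per-million, optionally log2.

    CPM scaling is computed over the genes present in the matrix (for
    cross-species work this is the shared orthologue universe, so per-sample
    totals are comparable between species).  ``log2_offset`` of ``x`` yields
    ``log2(cpm + x)``; None skips the log transform.
    """
    if method not in ("cpm", "none"):
        raise ConfigurationError(f"unknown normalisation method {method!r}")
    if log2_offset is not None and log2_offset < 0:
        raise ConfigurationError("log2_offset must be >= 0")
    if method == "none" and log2_offset is None:
        return matrix
    data = matrix.data
    unit = matrix.unit
    if method == "cpm":
        if matrix.unit != "raw":
            raise ConfigurationError(
                f"cpm normalisation needs raw counts, got unit {matrix.unit!r}"
            )
        totals = data.sum(axis=0, skipna=True)
        zero = totals.index[totals <= 0].tolist()
        if zero:
            raise ValidationError(f"all-zero sample(s): {zero}")
        data = data / totals * 1e6
        unit = "cpm"
    if log2_offset is not None:
        data = np.log2(data + log2_offset)
        unit = "log2cpm" if unit == "cpm" else unit
    return ExpressionMatrix(data, matrix.samples, unit)


def call_expressed(matrix: ExpressionMatrix, species: str, stage: str,
                   min_level: float = 1.0,
                   min_fraction: float = 0.5) -> set[str]:
    """Genes expressed in a (species, stage) group.

    A gene is called expressed iff its value is ``>= min_level`` in at least
    ``min_fraction`` of the group's samples.  Missing (NaN) genes are never
    called expressed.
    """
    ids = matrix.group_samples(species=species, stage_or_condition=stage)
    if not ids:
        raise ValidationError(f"no samples for species={species!r} stage={stage!r}")
    sub = matrix.data[ids]
    frac = (sub >= min_level).sum(axis=1) / len(ids)
    called = frac >= min_fraction
    # all-NaN rows produce frac 0, already excluded unless min_fraction == 0
    called &= sub.notna().any(axis=1)
    return set(sub.index[called])


def expressed_sets(matrix_by_species: Mapping[str, ExpressionMatrix],
                   stages: Iterable[str], min_level: float = 1.0,
                   min_fraction: float = 0.5) -> ExpressedSets:
    """Expressed calls for every species at every stage."""
    out: dict[tuple[str, str], set[str]] = {}
    universe: set[str] = set()
    for sp, mat in matrix_by_species.items():
        universe |= set(mat.genes)
        for st in stages:
            out[(sp, st)] = call_expressed(mat, sp, st, min_level, min_fraction)
    return ExpressedSets(out, min_level, min_fraction, universe)


def venn_regions(sets: Mapping[str, set]) -> dict:
    """Exclusive region counts and shared fractions for three gene sets.

    Returns a dict with:

    - ``regions``: mapping from a tuple of member labels (the labels whose
      sets contain the region, e.g. ``("mouse",)`` or
      ``("mouse", "pig", "bovine")``) to the count of genes exclusive to
      that region — 7 regions for 3 sets;
    - ``shared_fraction``: per label, |triple intersection| / |that set|
      (NaN for an empty set);
    - ``union``: size of the union.
    """
    labels = list(sets)
    if len(labels) != 3:
        raise ConfigurationError("venn_regions expects exactly three sets")
    a, b, c = (sets[l] for l in labels)
    union = a | b | c
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, 4):
        for combo in combinations(range(3), r):
            inside = set.intersection(*(sets[labels[i]] for i in combo))
            outside = set.union(
                set(), *(sets[labels[i]] for i in range(3) if i not in combo)
            )
            regions[tuple(labels[i] for i in combo)] = len(inside - outside)
    triple = len(a & b & c)
    shared = {
        l: (triple / len(sets[l]) if sets[l] else float("nan")) for l in labels
    }
    return {"regions": regions, "shared_fraction": shared, "union": len(union)}
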