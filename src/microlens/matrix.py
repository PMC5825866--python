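"""Core in-memory containers for expression data.

Expression matrices are genes x samples pandas DataFrames wrapped with a unit
tag (``counts`` or ``rpm``). Binary matrices hold top-k discretised profiles.
A marker compendium stores per-tissue marker gene sets over a shared universe
together with the parameters that built it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_UNITS = ("counts", "rpm")


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols, columns are unique sample
        labels, values non-negative reals.
    unit:
        ``"counts"`` for raw read counts, ``"rpm"`` for reads per million.
    """

    data: pd.DataFrame
    unit: str = "rpm"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample label {dup!r}")
        values = self.data.to_numpy()
        if values.size and (np.isnan(values).any() or (values < 0).any()):
            raise ValidationError("expression values must be non-negative and finite")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def column(self, label: str) -> pd.Series:
        from .errors import LookupError_

        if label not in self.data.columns:
            raise LookupError_(f"unknown sample label {label!r}")
        return self.data[label]

    def canonical(self) -> "ExpressionMatrix":
        """Return a copy with genes in canonical (lexicographic) order."""
        return ExpressionMatrix(self.data.sort_index(), unit=self.unit)


@dataclass
class BinaryMatrix:
    """Top-k discretised profiles: each column has exactly ``k_used`` ones."""

    data: pd.DataFrame  # {0,1} int8, genes x samples
    k_used: pd.Series  # per-sample count of ones

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0)
        if not (sums == self.k_used.reindex(sums.index)).all():
            raise ValidationError("column sums do not match k_used")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class MarkerCompendium:
    """Per-tissue marker gene sets over a shared gene universe.

    A gene is a marker for tissue *t* when it is among *t*'s ``top_m`` most
    highly expressed genes and is "highly expressed" (same top-m criterion) in
    at most a fraction ``spec_frac`` of all tissues.
    """

    marker_sets: dict[str, frozenset[str]]
    gene_universe: frozenset[str]
    top_m: int
    spec_frac: float
    top_lists: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tissue, markers in self.marker_sets.items():
            if not markers <= self.gene_universe:
                raise ValidationError(f"marker set of {tissue!r} escapes the gene universe")
            if len(markers) > self.top_m:
                raise ValidationError(f"marker set of {tissue!r} larger than top_m={self.top_m}")

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.marker_sets)
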