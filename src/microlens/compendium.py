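"""Compendium construction: RPM normalisation, replicate averaging, top-k
discretisation, ubiquity filtering, and tissue-specific marker-set building.

The chain implemented here turns raw expression matrices into (a) binary
profiles suitable for an asymmetric binary dissimilarity, and (b) a compendium
of tissue-specific marker gene sets for Fisher-exact identity scoring:

* per-sample library-size normalisation to reads per million (RPM);
* arithmetic averaging of replicate columns per tissue;
* harmonisation of matrices to a shared gene universe (symbol intersection);
* discretisation of each profile to 1 for its *k* (default 1000) most highly
  expressed genes, 0 otherwise — a rank-based batch-effect guard;
* removal of genes marked 1 in more than ``max_frac`` (default 20%) of
  profiles before distance computation;
* marker sets: a tissue's top ``top_m`` (default 3000) genes restricted to
  genes highly expressed in at most ``spec_frac`` (default 5%) of tissues.

Boundary semantics are exact fractions: the ubiquity filter removes strictly
above ``max_frac``; the specificity filter keeps at-or-below ``spec_frac``.
Ties at a top-k cutoff are broken by canonical (lexicographic) gene order.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, IncompatibilityError, ValidationError
from .matrix import BinaryMatrix, ExpressionMatrix, MarkerCompendium

RPM_SCALE = 1_000_000

DEFAULT_K = 1000
DEFAULT_MAX_UBIQUITY = 0.20
DEFAULT_TOP_M = 3000
DEFAULT_SPEC_FRAC = 0.05


def normalise_rpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to reads per million (columns sum to 10^6)."""
    if matrix.unit != "counts":
        raise ValidationError(f"normalise_rpm expects counts, got unit {matrix.unit!r}")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateInputError(f"sample {zero.index[0]!r} has zero total counts")
    return ExpressionMatrix(matrix.data * (RPM_SCALE / totals), unit="rpm")


def average_replicates(matrix: ExpressionMatrix, groups: dict[str, str]) -> ExpressionMatrix:
    """Average replicate columns: one output column per group, gene-wise mean.

    ``groups`` maps every sample label to its group (tissue) label.
    """
    missing = [s for s in matrix.samples if s not in groups]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} not assigned to any group")
    by_group: dict[str, list[str]] = {}
    for sample in matrix.samples:
        by_group.setdefault(groups[sample], []).append(sample)
    averaged = pd.DataFrame(
        {g: matrix.data[cols].mean(axis=1) for g, cols in by_group.items()},
        index=matrix.genes,
    )
    return ExpressionMatrix(averaged, unit=matrix.unit)


def harmonise_universe(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the shared gene symbols, in lexicographic order."""
    if not matrices:
        raise ValidationError("need at least one matrix")
    shared = set(matrices[0].genes)
    for m in matrices[1:]:
        shared &= set(m.genes)
    if not shared:
        raise IncompatibilityError("gene universes have empty intersection")
    order = sorted(shared)
    return [ExpressionMatrix(m.data.loc[order], unit=m.unit) for m in matrices]


def _top_k_indices(values: np.ndarray, order: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties at the cutoff broken by ``order``.

    ``order`` gives each gene's canonical rank (0 = first lexicographically).
    Sorting by (-value, canonical rank) makes the selection deterministic.
    """
    sorter = np.lexsort((order, -values))
    return sorter[:k]


def discretise_top_k(matrix: ExpressionMatrix, k: int = DEFAULT_K) -> BinaryMatrix:
    """Binarise each sample: 1 for its k most highly expressed genes, else 0."""
    n_genes = len(matrix.genes)
    if k > n_genes:
        raise ValidationError(f"k={k} exceeds the {n_genes}-gene universe")
    if k < 0:
        raise ValidationError("k must be non-negative")
    canonical_rank = np.argsort(np.argsort(matrix.genes.to_numpy()))
    bits = np.zeros(matrix.data.shape, dtype=np.int8)
    values = matrix.data.to_numpy()
    for j in range(values.shape[1]):
        bits[_top_k_indices(values[:, j], canonical_rank, k), j] = 1
    data = pd.DataFrame(bits, index=matrix.genes, columns=matrix.samples)
    return BinaryMatrix(data, k_used=pd.Series(k, index=matrix.samples))


def ubiquity_filter(bits: BinaryMatrix, max_frac: float = DEFAULT_MAX_UBIQUITY) -> frozenset[str]:
    """Genes retained for distance computation: marked 1 in <= max_frac of samples.

    Genes expressed (bit 1) in strictly more than ``max_frac`` of the profiles
    are removed; the boundary fraction itself is retained.
    """
    if not 0 <= max_frac <= 1:
        raise ValidationError("max_frac must lie in [0, 1]")
    frac = bits.data.mean(axis=1)
    return frozenset(frac.index[frac <= max_frac])


def build_marker_sets(
    matrix: ExpressionMatrix,
    top_m: int = DEFAULT_TOP_M,
    spec_frac: float = DEFAULT_SPEC_FRAC,
) -> MarkerCompendium:
    """Build per-tissue marker sets from a replicate-averaged matrix.

    For each tissue the candidate markers are its ``top_m`` most highly
    expressed genes; candidates present in the top-m list of more than
    ``spec_frac`` of tissues are discarded as non-specific.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("marker specificity is undefined for a single tissue")
    if top_m > len(matrix.genes):
        raise ValidationError(f"top_m={top_m} exceeds the {len(matrix.genes)}-gene universe")
    top_bits = discretise_top_k(matrix, k=top_m)
    n_tissues = len(matrix.samples)
    occupancy = top_bits.data.sum(axis=1)  # tissues whose top-m list holds each gene
    specific = occupancy / n_tissues <= spec_frac
    marker_sets: dict[str, frozenset[str]] = {}
    top_lists: dict[str, frozenset[str]] = {}
    for tissue in matrix.samples:
        in_top = top_bits.data[tissue] == 1
        top_lists[tissue] = frozenset(matrix.genes[in_top])
        marker_sets[tissue] = frozenset(matrix.genes[in_top & specific])
    return MarkerCompendium(
        marker_sets=marker_sets,
        gene_universe=frozenset(matrix.genes),
        top_m=top_m,
        spec_frac=spec_frac,
        top_lists=top_lists,
    )
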