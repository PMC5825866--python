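"""Cell-identity scoring of a query transcriptome against a tissue compendium.

Two complementary placements are computed:

1. **Ordination** — binary profiles (top-k discretised, ubiquity-filtered) are
   compared with the asymmetric binary dissimilarity (joint absences ignored,
   the convention of R's ``dist(..., method="binary")``), and the resulting
   matrix embedded by classical principal coordinates analysis (PCoA). The
   query's identity candidates are tissues ranked by Euclidean proximity in
   the positive-eigenvalue coordinate space.

2. **Marker-set enrichment** — the query's tissue-specific marker set is
   intersected with each compendium tissue's marker set; one-sided Fisher
   exact tests over the shared gene universe give per-tissue p-values, adjusted
   across tissues by the Benjamini-Hochberg step-up procedure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, IncompatibilityError, LookupError_, ValidationError
from .matrix import BinaryMatrix, ExpressionMatrix, MarkerCompendium
from .compendium import discretise_top_k


# ---------------------------------------------------------------------------
# binary dissimilarity
# ---------------------------------------------------------------------------

def binary_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """Asymmetric binary dissimilarity (b+c)/(a+b+c); joint absences ignored.

    a = positions on in both, b = on only in x, c = on only in y. Undefined
    (raises) when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    denom = int(np.count_nonzero(x | y))
    if denom == 0:
        raise DegenerateInputError("binary dissimilarity undefined for two all-zero vectors")
    a = int(np.count_nonzero(x & y))
    return (denom - a) / denom


def dissimilarity_matrix(bits: BinaryMatrix, retained_genes: frozenset[str] | set[str]) -> pd.DataFrame:
    """Pairwise binary dissimilarity over the retained genes only.

    Returns a symmetric DataFrame with zero diagonal, labelled by sample.
    """
    if not set(retained_genes) <= set(bits.genes):
        raise ValidationError("retained_genes must be a subset of the gene universe")
    order = sorted(retained_genes)
    sub = bits.data.loc[order].to_numpy(dtype=bool)
    labels = bits.samples
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = binary_dissimilarity(sub[:, i], sub[:, j])
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical PCoA embedding.

    ``coordinates`` holds one row per sample over the positive-eigenvalue
    axes (eigenvector scaled by sqrt eigenvalue, descending eigenvalue order);
    ``eigenvalues`` reports the full non-increasing spectrum, negative values
    included but never used for coordinates.
    """

    labels: list[str]
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray


def _validate_dissimilarity(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValidationError("dissimilarity matrix must have zero diagonal")
    if np.any(arr < 0):
        raise ValidationError("dissimilarity entries must be non-negative")
    return arr


def pcoa(d: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """Classical (Torgerson) principal coordinates of a dissimilarity matrix.

    Double-centres B = -1/2 * J (D∘D) J, eigendecomposes, and returns the
    eigenvectors scaled by the square roots of the positive eigenvalues.
    """
    arr = _validate_dissimilarity(d)
    n = arr.shape[0]
    if n_components is not None and n_components > n - 1:
        raise ValidationError("n_components must be at most n-1")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (arr**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    tol = max(1e-10, 1e-10 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_components is not None:
        coords = coords[:, :n_components]
    labels = list(d.index)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        labels=labels,
        coordinates=pd.DataFrame(coords, index=labels, columns=cols),
        eigenvalues=eigvals,
    )


def rank_by_proximity(ordination: OrdinationResult, query_label: str) -> pd.Series:
    """Tissues ordered by Euclidean distance to the query in the embedding.

    Uses every retained (positive-eigenvalue) component; ties broken by label.
    Returns distances indexed by tissue, ascending.
    """
    if query_label not in ordination.coordinates.index:
        raise LookupError_(f"unknown label {query_label!r}")
    coords = ordination.coordinates
    diff = coords - coords.loc[query_label]
    dist = np.sqrt((diff**2).sum(axis=1)).drop(query_label)
    frame = pd.DataFrame({"label": dist.index, "distance": dist.to_numpy()})
    frame = frame.sort_values(["distance", "label"], kind="mergesort")
    return frame.set_index("label")["distance"]


# ---------------------------------------------------------------------------
# marker-set enrichment
# ---------------------------------------------------------------------------

def query_marker_set(query: pd.Series, compendium: MarkerCompendium) -> frozenset[str]:
    """Tissue-specific marker set of a query expression profile.

    Applies the compendium's own top-m / specificity rule: the query's top_m
    genes, restricted to genes highly expressed in at most spec_frac of the
    compendium tissues. The query itself does not count towards specificity.
    """
    if set(query.index) != set(compendium.gene_universe):
        raise IncompatibilityError("query gene universe differs from the compendium's")
    qm = ExpressionMatrix(query.to_frame("query"))
    top = discretise_top_k(qm, k=compendium.top_m)
    top_genes = frozenset(top.genes[top.data["query"] == 1])
    n_tissues = len(compendium.top_lists)
    occupancy: dict[str, int] = {}
    for genes in compendium.top_lists.values():
        for g in genes:
            occupancy[g] = occupancy.get(g, 0) + 1
    return frozenset(
        g for g in top_genes if occupancy.get(g, 0) / n_tissues <= compendium.spec_frac
    )


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 table.

    P(overlap >= a) under the hypergeometric null with the observed margins:
    drawing a+b query genes from a universe of a+b+c+d containing a+c
    tissue-marker genes.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("2x2 counts must be non-negative")
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the original order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending sort order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


def fisher_enrichment(query_markers: frozenset[str] | set[str], compendium: MarkerCompendium) -> pd.DataFrame:
    """Per-tissue one-sided Fisher enrichment of the query marker set.

    Returns a DataFrame indexed by tissue with columns a, b, c, d, p_value,
    fdr (BH across the compendium's tissues) and rank (ascending fdr, ties by
    p then label), sorted by rank.
    """
    universe = compendium.gene_universe
    query_markers = frozenset(query_markers)
    if not query_markers:
        raise DegenerateInputError("query marker set is empty")
    if not query_markers <= universe:
        raise IncompatibilityError("query markers escape the compendium gene universe")
    n_universe = len(universe)
    rows = []
    for tissue, markers in compendium.marker_sets.items():
        a = len(query_markers & markers)
        b = len(query_markers) - a
        c = len(markers) - a
        d = n_universe - a - b - c
        rows.append((tissue, a, b, c, d, fisher_pvalue(a, b, c, d)))
    table = pd.DataFrame(rows, columns=["tissue", "a", "b", "c", "d", "p_value"]).set_index("tissue")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(["fdr", "p_value", "tissue"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def replicate_correlation(sample_a: pd.Series, sample_b: pd.Series, log_transform: bool = True) -> float:
    """Pearson correlation between two expression profiles.

    With ``log_transform`` (default) values are log2(x+1)-transformed first,
    the usual scale for library-to-library concordance.
    """
    if not sample_a.index.equals(sample_b.index):
        raise IncompatibilityError("samples must share an identical gene universe")
    x = sample_a.to_numpy(dtype=float)
    y = sample_b.to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x + 1), np.log2(y + 1)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined: <3 genes or zero variance")
    return float(stats.pearsonr(x, y).statistic)
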