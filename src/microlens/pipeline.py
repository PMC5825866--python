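"""End-to-end composition of the identity-scoring stages.

`score_query` runs the full chain the way the analyses use it: harmonise the
query with the compendium, average query replicates, discretise everything,
ubiquity-filter, embed by PCoA and rank tissues by proximity; in parallel,
build tissue marker sets and Fisher-score the query's own marker set against
them. The two rankings are independent reads on the same question — what is
this sample?
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import compendium as comp
from . import identity
from .matrix import ExpressionMatrix, MarkerCompendium

QUERY_LABEL = "query"


@dataclass
class IdentityScore:
    """Joint output of the ordination and enrichment arms."""

    dissimilarity: pd.DataFrame
    ordination: identity.OrdinationResult
    proximity: pd.Series  # tissues by ascending distance to the query
    markers: MarkerCompendium
    query_markers: frozenset[str]
    enrichment: pd.DataFrame

    @property
    def top_by_proximity(self) -> str:
        return str(self.proximity.index[0])

    @property
    def top_by_enrichment(self) -> str:
        return str(self.enrichment.index[0])


def score_query(
    compendium_matrix: ExpressionMatrix,
    query: ExpressionMatrix,
    k: int = comp.DEFAULT_K,
    max_ubiquity: float = comp.DEFAULT_MAX_UBIQUITY,
    top_m: int = comp.DEFAULT_TOP_M,
    spec_frac: float = comp.DEFAULT_SPEC_FRAC,
) -> IdentityScore:
    """Score a (possibly replicated) query against a tissue compendium.

    Query replicates are averaged into a single profile before scoring. The
    query profile participates in the ubiquity filter as one dataset among
    the compared profiles; it does not count towards marker specificity.
    """
    tissues, query = comp.harmonise_universe([compendium_matrix, query])
    query_profile = comp.average_replicates(
        query, {s: QUERY_LABEL for s in query.samples}
    )
    combined = ExpressionMatrix(
        tissues.data.join(query_profile.data), unit=tissues.unit
    )
    bits = comp.discretise_top_k(combined, k=k)
    retained = comp.ubiquity_filter(bits, max_frac=max_ubiquity)
    dmat = identity.dissimilarity_matrix(bits, retained)
    ordination = identity.pcoa(dmat)
    proximity = identity.rank_by_proximity(ordination, QUERY_LABEL)

    markers = comp.build_marker_sets(tissues, top_m=top_m, spec_frac=spec_frac)
    query_markers = identity.query_marker_set(query_profile.data[QUERY_LABEL], markers)
    enrichment = identity.fisher_enrichment(query_markers, markers)
    return IdentityScore(
        dissimilarity=dmat,
        ordination=ordination,
        proximity=proximity,
        markers=markers,
        query_markers=query_markers,
        enrichment=enrichment,
    )
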