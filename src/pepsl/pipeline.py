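"""High-level drivers chaining the discovery stages end to end."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import DEFAULT_GAP, SubstitutionMatrix, load_substitution_matrix
from .clustering import (
    DEFAULT_PROFILE_EVALUE,
    PeptideCluster,
    assign_clusters,
    cluster_all,
    dedupe_clusters,
    filter_clusters,
    merge_clusters,
)
from .significance import DEFAULT_P_THRESHOLD, SignificantPair, find_significant_pairs
from .windows import ProteinRecord, WindowCatalog, chop_proteome

__all__ = ["ClusterDiscovery", "discover_clusters"]


@dataclass
class ClusterDiscovery:
    """Everything produced by one run of the cluster-discovery pipeline."""

    catalog: WindowCatalog
    pairs: list[SignificantPair]
    grown: list[PeptideCluster]
    deduped: list[PeptideCluster]
    clusters: list[PeptideCluster]
    assignment: dict[str, frozenset[str]]


def discover_clusters(
    records: Sequence[ProteinRecord],
    L: int = 25,
    w: int = 5,
    matrix: SubstitutionMatrix | None = None,
    gap_penalty: int = DEFAULT_GAP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    evalue_threshold: float = DEFAULT_PROFILE_EVALUE,
    merge_rule: str = "frac10",
    min_members: int = 3,
    max_proteins: int | None = 50,
) -> ClusterDiscovery:
    """Run chop -> significant pairs -> grow -> dedupe/merge/filter.

    Returns every intermediate stage so callers can evaluate or re-post-process
    (e.g. try a different merge rule on the same deduped clusters).
    """
    matrix = matrix or load_substitution_matrix("BLOSUM62")
    catalog = chop_proteome(records, L=L, w=w)
    pairs = find_significant_pairs(catalog, matrix, gap_penalty, p_threshold)
    grown = cluster_all(pairs, catalog, evalue_threshold)
    deduped = dedupe_clusters(grown)
    clusters = filter_clusters(
        merge_clusters(deduped, merge_rule),
        min_members=min_members,
        max_proteins=max_proteins,
    )
    return ClusterDiscovery(
        catalog=catalog,
        pairs=pairs,
        grown=grown,
        deduped=deduped,
        clusters=clusters,
        assignment=assign_clusters(clusters),
    )
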