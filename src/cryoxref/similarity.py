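"""Entry-to-entry similarity by annotation-neighborhood overlap.

Entries and their biological annotations form a bipartite graph: entry
nodes on one side, (resource, accession) nodes on the other.  Two entries
are similar when their annotation neighborhoods overlap; the strength is
the Jaccard coefficient of the two neighbor sets.  Citation-identifier
resources (PubMed, PMC, DOI, ISSN, ORCiD) are excluded from the
neighborhood so shared journals or authors do not drive similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .model import Annotation, CITATION_RESOURCES, EntryId

DEFAULT_MIN_COEFFICIENT = 0.0
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class SimilarityRecord:
    """A scored pair of entries and the annotations they share."""

    entry_a: EntryId
    entry_b: EntryId
    coefficient: float
    shared: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.entry_a == self.entry_b:
            raise ValueError("an entry cannot be similar to itself")
        if not (0.0 < self.coefficient <= 1.0):
            raise ValueError(f"coefficient must be in (0, 1], got {self.coefficient}")


def build_graph(annotations: Iterable[Annotation]) -> nx.Graph:
    """Bipartite graph of entry nodes (bipartite=0) and (resource,
    accession) annotation nodes (bipartite=1)."""
    graph = nx.Graph()
    for ann in annotations:
        if ann.resource in CITATION_RESOURCES:
            continue
        entry_node = str(ann.entry_id)
        ann_node = (ann.resource, ann.accession)
        graph.add_node(entry_node, bipartite=0)
        graph.add_node(ann_node, bipartite=1)
        graph.add_edge(entry_node, ann_node)
    return graph


def neighborhood(graph: nx.Graph, entry_id: EntryId | str) -> frozenset[tuple[str, str]]:
    """The (resource, accession) neighbor set of one entry node."""
    return frozenset(graph[str(entry_id)])


def similar_entries(
    entry_id: EntryId | str,
    graph: nx.Graph,
    min_coefficient: float = DEFAULT_MIN_COEFFICIENT,
    top_k: int = DEFAULT_TOP_K,
) -> list[SimilarityRecord]:
    """Entries whose neighborhoods overlap the query entry's, ranked by
    Jaccard coefficient descending (ties by entry id ascending) and
    truncated to ``top_k``.  The query entry never appears in its own
    results.  Raises ``KeyError`` when the entry is not in the graph."""
    entry_id = str(EntryId(entry_id))
    if entry_id not in graph:
        raise KeyError(f"entry {entry_id} not in similarity graph")
    n_query = set(graph[entry_id])

    candidates: set[str] = set()
    for ann_node in n_query:
        candidates.update(graph[ann_node])
    candidates.discard(entry_id)

    records = []
    for other in candidates:
        n_other = set(graph[other])
        shared = n_query & n_other
        if not shared:
            continue
        coefficient = len(shared) / len(n_query | n_other)
        if coefficient >= min_coefficient and coefficient > 0.0:
            records.append(
                SimilarityRecord(
                    entry_a=EntryId(entry_id),
                    entry_b=EntryId(other),
                    coefficient=coefficient,
                    shared=frozenset(shared),
                )
            )
    records.sort(key=lambda r: (-r.coefficient, str(r.entry_b)))
    return records[:top_k]
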