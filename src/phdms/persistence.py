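"""Zero-dimensional persistent homology of the cluster filtration.

All vertices enter the filtration at value 0; edges enter in increasing
order of overlap dissimilarity. Processing the sorted edge list through a
union-find structure records, for each merge of two distinct components,
the death of one of them at that edge's weight. Since every component is
born at 0, the classical elder rule is ambiguous; the survivor is the class
containing the node with the smallest ``(scale_index, cluster_label)`` key,
which makes the output reproducible. Components still alive after the last
edge receive infinite death and, by convention, lifetime 1.

A component's member clusters are snapshotted immediately before its death
(at termination for survivors): after its death the feature no longer
exists, and this keeps the coreness scores consistent with the component's
lifetime. Its internal edges are the processed edges with both endpoints in
the snapshot and weight strictly below the death value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .filtration import ClusterFiltration, ClusterNode, OverlapEdge

__all__ = [
    "DiagramPoint",
    "PersistentComponent",
    "compute_persistence",
    "filter_components",
    "diagram_frame",
]


@dataclass(frozen=True)
class DiagramPoint:
    """One point of the 0-dimensional persistence diagram (birth always 0)."""

    birth: float
    death: float  # math.inf for surviving components
    component_id: int

    @property
    def lifetime(self) -> float:
        """Death minus birth, clamped to 1 for components that live forever."""
        return min(self.death, 1.0) - self.birth


@dataclass(frozen=True)
class PersistentComponent:
    """A connected component of the filtration with recovered membership."""

    id: int
    representative: tuple[int, int]
    death: float
    member_clusters: tuple[ClusterNode, ...]
    internal_edges: tuple[OverlapEdge, ...]

    birth: float = 0.0

    @property
    def lifetime(self) -> float:
        return min(self.death, 1.0) - self.birth

    @property
    def n_clusters(self) -> int:
        return len(self.member_clusters)


def compute_persistence(
    filt: ClusterFiltration,
) -> tuple[list[DiagramPoint], list[PersistentComponent]]:
    """Union-find 0-D persistence over the sorted edge list.

    Returns one diagram point per node: one finite point per merge (weight-0
    merges yield zero-persistence points, retained here and filterable
    downstream) and exactly one infinite point per final connected
    component.
    """
    keys = sorted(filt.nodes)
    parent = {k: k for k in keys}
    # per-root state: elder key, member keys, internal edges
    elder = {k: k for k in keys}
    members: dict[tuple[int, int], list] = {k: [k] for k in keys}
    internal: dict[tuple[int, int], list] = {k: [] for k in keys}

    def find(k):
        root = k
        while parent[root] != root:
            root = parent[root]
        while parent[k] != root:
            parent[k], k = root, parent[k]
        return root

    diagram: list[DiagramPoint] = []
    components: list[PersistentComponent] = []

    def record_death(root, weight: float) -> None:
        cid = len(components)
        snapshot = tuple(filt.nodes[k] for k in sorted(members[root]))
        edges = tuple(e for e in internal[root] if e.weight < weight)
        components.append(
            PersistentComponent(
                id=cid,
                representative=elder[root],
                death=weight,
                member_clusters=snapshot,
                internal_edges=edges,
            )
        )
        diagram.append(DiagramPoint(0.0, weight, cid))

    for edge in filt.edges:
        ru, rv = find(edge.source), find(edge.target)
        if ru == rv:
            internal[ru].append(edge)
            continue
        # the class with the larger elder key dies at this edge's weight
        if elder[rv] < elder[ru]:
            ru, rv = rv, ru
        record_death(rv, edge.weight)
        parent[rv] = ru
        members[ru].extend(members.pop(rv))
        internal[ru].extend(internal.pop(rv))
        internal[ru].append(edge)

    for root in sorted(set(find(k) for k in keys)):
        cid = len(components)
        snapshot = tuple(filt.nodes[k] for k in sorted(members[root]))
        components.append(
            PersistentComponent(
                id=cid,
                representative=elder[root],
                death=math.inf,
                member_clusters=snapshot,
                internal_edges=tuple(internal[root]),
            )
        )
        diagram.append(DiagramPoint(0.0, math.inf, cid))

    return diagram, components


def filter_components(
    components: list[PersistentComponent],
    min_lifetime: float = 0.0,
    min_clusters: int = 1,
) -> list[PersistentComponent]:
    """Components with lifetime >= ``min_lifetime`` and at least
    ``min_clusters`` member clusters, in the original order."""
    if not 0.0 <= min_lifetime <= 1.0:
        raise ValueError("min_lifetime must lie in [0, 1]")
    if min_clusters < 1:
        raise ValueError("min_clusters must be at least 1")
    return [
        c
        for c in components
        if c.lifetime >= min_lifetime and c.n_clusters >= min_clusters
    ]


def diagram_frame(
    diagram: list[DiagramPoint], components: list[PersistentComponent]
) -> pd.DataFrame:
    """Tabular persistence diagram with per-component sizes."""
    by_id = {c.id: c for c in components}
    rows = []
    for pt in diagram:
        comp = by_id[pt.component_id]
        n_spots = len({int(s) for node in comp.member_clusters for s in node.members})
        rows.append(
            {
                "component_id": pt.component_id,
                "birth": pt.birth,
                "death": "inf" if math.isinf(pt.death) else pt.death,
                "lifetime": pt.lifetime,
                "n_clusters": comp.n_clusters,
                "n_spots": n_spots,
            }
        )
    return pd.DataFrame(rows)
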