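import numpy as np
import pytest

from phdms import ClusteringSequence, ScaleClustering, SpotSet


@pytest.fixture
def toy_spots() -> SpotSet:
    """Five spots on a line; the worked two-scale example lives on these."""
    ids = np.array(["s1", "s2", "s3", "s4", "s5"], dtype=object)
    coords = np.column_stack([np.arange(5, dtype=float), np.zeros(5)])
    return SpotSet(ids, coords)


@pytest.fixture
def toy_sequence(toy_spots) -> ClusteringSequence:
    """Fine scale {s1..s3 | s4,s5}, coarse scale {s1..s4 | s5}.

    Containment weights of the three overlapping pairs are {0, 0.5, 0.5};
    the persistence diagram is {(0,0), (0,0.5), (0,0.5), (0,inf)} and the
    immortal component's normalized coreness is [1, 1, 1, 1, 0].
    """
    return ClusteringSequence(
        toy_spots,
        (
            ScaleClustering(0, 0.95, np.array([0, 0, 0, 1, 1])),
            ScaleClustering(1, 0.15, np.array([0, 0, 0, 0, 1])),
        ),
    )


def random_filtration(rng, max_nodes=30, max_edges=60):
    """A random edge-weighted graph wrapped as a cluster filtration.

    Node keys are (0, v); weights are distinct uniforms in (0, 1). Used to
    check union-find persistence against brute-force component counting.
    """
    from phdms.filtration import ClusterFiltration, ClusterNode, OverlapEdge

    n = int(rng.integers(2, max_nodes + 1))
    nodes = {
        (0, v): ClusterNode(0, v, np.array([v])) for v in range(n)
    }
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)]
    k = min(int(rng.integers(0, max_edges + 1)), len(pairs))
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
    weights = rng.random(k)
    edges = [
        OverlapEdge((0, u), (0, v), float(w), 1)
        for (u, v), w in zip(chosen, weights)
    ]
    edges.sort(key=lambda e: e.sort_key)
    return ClusterFiltration(nodes=nodes, edges=tuple(edges), index_kind="containment", n_spots=n)


def brute_force_component_counts(filt, thresholds):
    """Connected components of each threshold subgraph, the slow way."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    keys = sorted(filt.nodes)
    pos = {k: i for i, k in enumerate(keys)}
    counts = []
    for t in thresholds:
        rows, cols = [], []
        for e in filt.edges:
            if e.weight <= t:
                rows.append(pos[e.source])
                cols.append(pos[e.target])
        adj = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(keys), len(keys))
        )
        counts.append(connected_components(adj, directed=False)[0])
    return counts
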