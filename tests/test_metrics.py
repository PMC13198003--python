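import math

import numpy as np
import pytest

from phdms import (
    GroundTruthAnnotation,
    SpotSet,
    best_matching_scale,
    domain_matrix,
    match_to_truth,
    multiscale_nmi,
    select_best_subset,
    to_distribution,
    truth_matrix,
    wasserstein2,
)
from phdms.metrics import SpatialDistribution


def _spots(coords):
    coords = np.asarray(coords, dtype=float)
    ids = np.array([f"s{i}" for i in range(len(coords))], dtype=object)
    return SpotSet(ids, coords)


def _dist(weights, coords):
    return SpatialDistribution(np.asarray(weights, float), np.asarray(coords, float))


# -- distributions ----------------------------------------------------------


def test_to_distribution_binary_and_soft(toy_spots):
    binary = to_distribution(np.array([0, 1, 2, 3]), toy_spots)
    assert binary.weights.tolist() == [0.25, 0.25, 0.25, 0.25, 0.0]

    from phdms import build_overlap_graph, compute_coreness, compute_persistence

    with pytest.raises(ValueError):
        to_distribution(np.array([], dtype=int), toy_spots)


def test_soft_distribution_from_worked_example(toy_sequence):
    from phdms import build_overlap_graph, compute_coreness, compute_persistence

    filt = build_overlap_graph(toy_sequence)
    _, comps = compute_persistence(filt)
    immortal = next(c for c in comps if math.isinf(c.death))
    domain = compute_coreness(immortal, toy_sequence.spots)
    dist = to_distribution(domain, toy_sequence.spots)
    assert dist.weights.tolist() == [0.25, 0.25, 0.25, 0.25, 0.0]
    assert dist.weights.sum() == pytest.approx(1.0, abs=1e-12)


# -- Wasserstein ------------------------------------------------------------


def test_wasserstein_closed_forms():
    coords = [[0, 0], [3, 4]]
    pm0 = _dist([1, 0], coords)
    pm1 = _dist([0, 1], coords)
    assert wasserstein2(pm0, pm0) == 0.0
    assert wasserstein2(pm0, pm1) == pytest.approx(5.0, abs=1e-8)

    coords = [[0, 0], [1, 0]]
    uniform = _dist([0.5, 0.5], coords)
    point = _dist([1, 0], coords)
    assert wasserstein2(uniform, point) == pytest.approx(math.sqrt(0.5), abs=1e-8)


def test_wasserstein_is_a_metric_on_random_triples():
    rng = np.random.default_rng(0)
    coords = rng.random((12, 2)) * 10
    for _ in range(25):
        dists = []
        for _ in range(3):
            w = rng.random(12)
            dists.append(_dist(w / w.sum(), coords))
        a, b, c = dists
        ab, ba = wasserstein2(a, b), wasserstein2(b, a)
        assert ab == pytest.approx(ba, abs=1e-8)
        ac, cb = wasserstein2(a, c), wasserstein2(c, b)
        assert ab <= ac + cb + 1e-8
    # translation invariance
    w1 = rng.random(12)
    w2 = rng.random(12)
    d1 = _dist(w1 / w1.sum(), coords)
    d2 = _dist(w2 / w2.sum(), coords)
    shifted = coords + [100.0, -40.0]
    s1 = _dist(w1 / w1.sum(), shifted)
    s2 = _dist(w2 / w2.sum(), shifted)
    assert wasserstein2(d1, d2) == pytest.approx(wasserstein2(s1, s2), abs=1e-6)


def test_wasserstein_frame_mismatch_rejected():
    d1 = _dist([1.0], [[0, 0]])
    d2 = _dist([1.0], [[1, 1]])
    with pytest.raises(ValueError, match="frame"):
        wasserstein2(d1, d2)


def test_wasserstein_subsampling_is_seeded():
    rng = np.random.default_rng(1)
    coords = rng.random((60, 2)) * 10
    w1, w2 = rng.random(60), rng.random(60)
    d1 = _dist(w1 / w1.sum(), coords)
    d2 = _dist(w2 / w2.sum(), coords)
    a = wasserstein2(d1, d2, subsample_threshold=30, seed=5)
    b = wasserstein2(d1, d2, subsample_threshold=30, seed=5)
    assert a == b
    full = wasserstein2(d1, d2)
    assert abs(a - full) < 2.0  # subsample stays in the right ballpark


# -- generalized NMI --------------------------------------------------------


def _one_hot(labels):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float)


def test_nmi_identical_partitions_and_independence():
    labels = np.array([0, 0, 1, 1, 2, 2])
    assert multiscale_nmi(_one_hot(labels), _one_hot(labels)) == pytest.approx(1.0)

    d = _one_hot([0, 0, 1, 1])
    e = _one_hot([0, 1, 0, 1])
    assert multiscale_nmi(d, e) == pytest.approx(0.0, abs=1e-12)


def test_nmi_reduces_to_classical_on_binary_partitions():
    """Independent oracle: scikit-learn's arithmetic-mean NMI."""
    from sklearn.metrics import normalized_mutual_info_score

    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(10, 201))
        a = rng.integers(0, rng.integers(2, 9), n)
        b = rng.integers(0, rng.integers(2, 9), n)
        ours = multiscale_nmi(_one_hot(a), _one_hot(b))
        ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
        assert ours == pytest.approx(ref, abs=1e-10)


def test_nmi_symmetry_and_invariances():
    rng = np.random.default_rng(9)
    d = rng.random((50, 4))
    e = rng.random((50, 3))
    assert multiscale_nmi(d, e) == pytest.approx(multiscale_nmi(e, d), abs=1e-12)
    perm = rng.permutation(4)
    assert multiscale_nmi(d[:, perm], e) == pytest.approx(
        multiscale_nmi(d, e), abs=1e-12
    )


def test_nmi_degenerate_and_zero_rows():
    with pytest.warns(UserWarning):
        assert multiscale_nmi(np.ones((5, 1)), np.ones((5, 1))) == 0.0
    # all-zero rows are dropped from both sides
    d = _one_hot([0, 0, 1, 1])
    e = _one_hot([0, 0, 1, 1])
    d_padded = np.vstack([d, np.zeros((2, 2))])
    e_padded = np.vstack([e, np.ones((2, 2))])
    assert multiscale_nmi(d_padded, e_padded) == pytest.approx(
        multiscale_nmi(d, e)
    )
    with pytest.raises(ValueError, match="rows"):
        multiscale_nmi(d, np.zeros((7, 2)))


# -- benchmarking procedures ------------------------------------------------


def _truth(spots, labels):
    return GroundTruthAnnotation(spots=spots, labels=np.asarray(labels, object))


def test_match_to_truth_prefers_exact_copy(toy_sequence):
    from phdms import MultiscaleDomainModel

    results = MultiscaleDomainModel(toy_sequence).fit(min_clusters=1)
    truth = _truth(toy_sequence.spots, ["A", "A", "A", "A", "B"])
    matches = results.match_to_truth(truth)
    assert matches["A"][1] == pytest.approx(0.0)
    assert set(matches) == {"A", "B"}


def test_select_best_subset_recovers_truth_domains():
    rng = np.random.default_rng(2)
    spots = _spots(rng.random((40, 2)))
    labels = rng.integers(0, 3, 40)
    truth = _truth(spots, [f"d{v}" for v in labels])

    from phdms.domains import MultiscaleDomain
    from phdms.persistence import PersistentComponent

    def binary_domain(i, members):
        cbar = np.zeros(40)
        cbar[members] = 1.0
        comp = PersistentComponent(
            id=i, representative=(0, i), death=math.inf,
            member_clusters=(), internal_edges=(),
        )
        return MultiscaleDomain(comp, cbar.copy(), cbar)

    candidates = [
        binary_domain(i, members)
        for i, members in enumerate(truth.domains().values())
    ]
    subset, nmi = select_best_subset(candidates, truth)
    assert nmi == pytest.approx(1.0)
    assert {d.id for d in subset} == {0, 1, 2}

    single, single_nmi = select_best_subset(candidates, truth, max_size=1)
    assert len(single) == 1
    assert single_nmi <= nmi + 1e-12

    # greedy dominates every single-domain choice
    g = truth_matrix(truth)
    for cand in candidates:
        alone = multiscale_nmi(domain_matrix([cand], spots), g)
        assert nmi >= alone - 1e-12


def test_best_matching_scale(toy_spots):
    from phdms import ClusteringSequence, ScaleClustering

    def seq_with_counts(counts):
        scales = []
        for i, k in enumerate(counts):
            labels = (np.arange(5) % k).astype(np.int64)
            scales.append(ScaleClustering(i, 1.0 - 0.2 * i, labels))
        return ClusteringSequence(toy_spots, tuple(scales))

    truth3 = _truth(toy_spots, ["a", "a", "b", "b", "c"])
    assert best_matching_scale(seq_with_counts([5, 4, 3, 2]), truth3) == 2
    # tie between counts 2 and 4 resolves to the finer scale
    assert best_matching_scale(seq_with_counts([4, 2]), truth3) == 0
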