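import math

import numpy as np
import pytest

from phdms import (
    argmax_labels,
    build_overlap_graph,
    compute_coreness,
    compute_persistence,
    heterogeneity_map,
    normalize_coreness,
    rank_domains,
)
from phdms.domains import MultiscaleDomain


def _immortal_domain(toy_sequence):
    filt = build_overlap_graph(toy_sequence, "containment")
    _, components = compute_persistence(filt)
    comp = next(c for c in components if math.isinf(c.death))
    return compute_coreness(comp, toy_sequence.spots)


def test_worked_example_coreness(toy_sequence):
    domain = _immortal_domain(toy_sequence)
    assert domain.coreness.tolist() == [1.0, 1.0, 1.0, 1.0, 0.5]
    assert domain.normalized_coreness.tolist() == [1.0, 1.0, 1.0, 1.0, 0.0]
    assert domain.support_size == 5


def test_singleton_component_gets_unit_coreness(toy_sequence):
    filt = build_overlap_graph(toy_sequence)
    _, components = compute_persistence(filt)
    singleton = next(c for c in components if not c.internal_edges)
    domain = compute_coreness(singleton, toy_sequence.spots)
    members = {int(s) for n in singleton.member_clusters for s in n.members}
    for pos in range(toy_sequence.spots.n):
        expected = 1.0 if pos in members else 0.0
        assert domain.coreness[pos] == expected


def test_normalization_constant_and_idempotent(toy_sequence):
    domain = _immortal_domain(toy_sequence)
    twice = normalize_coreness(domain)
    assert twice.normalized_coreness.tolist() == domain.normalized_coreness.tolist()

    constant = MultiscaleDomain(
        component=domain.component,
        coreness=np.array([0.7, 0.7, 0.0]),
        normalized_coreness=np.zeros(3),
    )
    out = normalize_coreness(constant)
    assert out.normalized_coreness.tolist() == [1.0, 1.0, 0.0]

    empty = MultiscaleDomain(
        component=domain.component,
        coreness=np.zeros(3),
        normalized_coreness=np.zeros(3),
    )
    with pytest.raises(ValueError, match="support"):
        normalize_coreness(empty)


def _fake_domain(component, cbar, lifetime_death):
    from phdms.persistence import PersistentComponent

    comp = PersistentComponent(
        id=component,
        representative=(0, 0),
        death=lifetime_death,
        member_clusters=(),
        internal_edges=(),
    )
    cbar = np.asarray(cbar, dtype=float)
    return MultiscaleDomain(comp, cbar.copy(), cbar)


def test_heterogeneity_hand_values():
    d1 = _fake_domain(0, [1, 1, 0, 0], math.inf)  # lifetime 1
    h = heterogeneity_map([d1])
    assert h.tolist() == [1.0, 1.0, 0.0, 0.0]

    d2 = _fake_domain(1, [1, 0, 1, 0], 0.5)
    h = heterogeneity_map([d1, d2])
    assert h.tolist() == [1.5, 1.0, 0.5, 0.0]
    # invariant to list order
    assert heterogeneity_map([d2, d1]).tolist() == h.tolist()


def test_heterogeneity_matches_independent_per_spot_resummation():
    rng = np.random.default_rng(5)
    domains = [
        _fake_domain(i, rng.random(30), float(rng.uniform(0.1, 0.9)))
        for i in range(6)
    ]
    h = heterogeneity_map(domains)
    for x in range(30):
        expected = sum(d.lifetime * d.normalized_coreness[x] for d in domains)
        assert h[x] == pytest.approx(expected, abs=1e-12)
    assert (h <= sum(d.lifetime for d in domains) + 1e-12).all()


def test_rank_domains_by_weighted_persistence():
    specs = [(1.0, 100), (0.9, 50), (1.0, 10)]
    domains = []
    for i, (p, size) in enumerate(specs):
        cbar = np.zeros(120)
        cbar[:size] = 1.0
        domains.append(_fake_domain(i, cbar, math.inf if p == 1.0 else p))
    ranked = rank_domains(domains, top_k=10)
    assert [d.id for d in ranked] == [0, 1, 2]
    assert rank_domains(domains, top_k=2) == ranked[:2]
    # equal scores break ties toward the lower id
    tied = [_fake_domain(3, np.ones(10), math.inf), _fake_domain(2, np.ones(10), math.inf)]
    assert [d.id for d in rank_domains(tied, 5)] == [2, 3]
    with pytest.raises(ValueError):
        rank_domains(domains, top_k=0)


def test_argmax_labels():
    d0 = _fake_domain(0, [1.0, 0.2, 0.0], math.inf)
    d1 = _fake_domain(1, [0.3, 0.9, 0.0], math.inf)
    labels = argmax_labels([d0, d1])
    assert labels.tolist() == [0, 1, -1]
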