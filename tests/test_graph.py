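"""Tier classification, dyad derivation, density, and clique enumeration.

The clique oracle is an independent brute force over all node subsets.
"""

from datetime import date, datetime
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peernet.graph import (
    DyadicInteraction,
    EngagementTier,
    InteractionGraph,
    build_graph,
    classify_tier,
    density,
    derive_dyads,
    export_graph,
    maximal_cliques,
)
from peernet.io_model import CommunicationEvent, EngagementError, EventKind

from conftest import make_log, make_member


def brute_force_maximal_cliques(nodes, edges):
    """Enumerate all subsets; keep cliques with no strict clique superset."""
    nodes = sorted(nodes)
    eset = {frozenset(e) for e in edges}
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(frozenset(p) in eset for p in combinations(sub, 2)):
                cliques.append(frozenset(sub))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return sorted((tuple(sorted(c)) for c in maximal), key=lambda c: (-len(c), c))


@pytest.mark.parametrize(
    "kind,tier",
    [
        (EventKind.POST, EngagementTier.HIGH),
        (EventKind.COMMENT, EngagementTier.HIGH),
        (EventKind.POLL, EngagementTier.HIGH),
        (EventKind.REACTION, EngagementTier.MEDIUM),
        (EventKind.VOTE, EngagementTier.MEDIUM),
        (EventKind.VIEW, EngagementTier.LOW),
    ],
)
def test_tier_classification_is_total(kind, tier):
    assert classify_tier(kind) is tier


def test_dyads_from_comment_chain():
    t = datetime(2020, 2, 1)
    members = [make_member(m) for m in "ABCD"]
    events = [
        CommunicationEvent("p1", "A", EventKind.POST, t),
        CommunicationEvent("c1", "B", EventKind.COMMENT, t, "p1"),
        CommunicationEvent("r1", "C", EventKind.REACTION, t, "c1"),
        CommunicationEvent("v1", "D", EventKind.VIEW, t, "p1"),
    ]
    log = make_log(members, events)
    dyads = derive_dyads(log)
    got = {(d.pair, d.tier) for d in dyads}
    assert got == {
        (("A", "B"), EngagementTier.HIGH),
        (("B", "C"), EngagementTier.MEDIUM),
    }


def test_self_comment_yields_no_dyad():
    t = datetime(2020, 2, 1)
    log = make_log(
        [make_member("A")],
        [
            CommunicationEvent("p1", "A", EventKind.POST, t),
            CommunicationEvent("c1", "A", EventKind.COMMENT, t, "p1"),
        ],
    )
    assert derive_dyads(log) == []


def test_views_never_influence_dyads():
    t = datetime(2020, 2, 1)
    members = [make_member(m) for m in "AB"]
    base = [
        CommunicationEvent("p1", "A", EventKind.POST, t),
        CommunicationEvent("c1", "B", EventKind.COMMENT, t, "p1"),
    ]
    views = [
        CommunicationEvent(f"v{i}", "B", EventKind.VIEW, t, "p1") for i in range(50)
    ]
    assert derive_dyads(make_log(members, base)) == derive_dyads(
        make_log(members, base + views)
    )


def _dyad(a, b, ts, tier=EngagementTier.HIGH, src="x"):
    return DyadicInteraction(a, b, tier, ts, src)


def test_build_graph_aggregates_and_respects_half_open_window():
    t0, t1 = datetime(2020, 1, 1), datetime(2020, 2, 1)
    dyads = [
        _dyad("A", "B", datetime(2020, 1, 10)),
        _dyad("B", "A", datetime(2020, 1, 20)),
        _dyad("A", "B", t1),  # exactly at window end -> excluded
    ]
    g = build_graph(dyads, (t0, t1), {"A", "B", "C"})
    assert g.multi_edge_counts == {("A", "B"): 2}
    assert g.nodes == {"A", "B", "C"}


def test_build_graph_rejects_foreign_member():
    with pytest.raises(EngagementError, match="Z"):
        build_graph(
            [_dyad("A", "Z", datetime(2020, 1, 5))],
            (datetime(2020, 1, 1), datetime(2020, 2, 1)),
            {"A", "B"},
        )


def test_density_examples():
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    g = InteractionGraph({1, 2, 3, 4}, {(1, 2): 1, (1, 3): 2}, win)
    assert density(g) == pytest.approx(2 / 6)
    complete = InteractionGraph(set(range(5)), {p: 1 for p in combinations(range(5), 2)}, win)
    assert density(complete) == 1.0
    assert density(InteractionGraph(set(range(10)), {}, win)) == 0.0
    with pytest.raises(EngagementError):
        density(InteractionGraph({1}, {}, win))


def test_density_monotone_under_edge_addition():
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    nodes = set(range(6))
    edges = {}
    prev = 0.0
    for pair in combinations(range(6), 2):
        edges[pair] = 1
        d = density(InteractionGraph(nodes, dict(edges), win))
        assert d >= prev
        prev = d
    # adding an isolated node strictly decreases density when edges exist
    d_before = density(InteractionGraph(nodes, {(0, 1): 1}, win))
    d_after = density(InteractionGraph(nodes | {99}, {(0, 1): 1}, win))
    assert d_after < d_before


def test_cliques_triangle_plus_pendant():
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    g = InteractionGraph({1, 2, 3, 4}, {(1, 2): 1, (1, 3): 1, (2, 3): 1, (3, 4): 1}, win)
    assert maximal_cliques(g) == [(1, 2, 3), (3, 4)]


def test_cliques_edgeless_graph_gives_singletons():
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    g = InteractionGraph({1, 2, 3}, {}, win)
    assert maximal_cliques(g) == [(1,), (2,), (3,)]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=2, max_value=12))
def test_cliques_equal_brute_force_on_random_graphs(seed, n):
    rng = np.random.default_rng(seed)
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    edges = {
        pair: 1 for pair in combinations(range(n), 2) if rng.random() < 0.4
    }
    g = InteractionGraph(set(range(n)), edges, win)
    got = maximal_cliques(g)
    assert got == brute_force_maximal_cliques(range(n), edges)
    # direct clique/maximality assertions
    eset = set(edges)
    for c in got:
        assert all(tuple(sorted(p)) in eset for p in combinations(c, 2))


def test_export_graphml_roundtrips_through_networkx(tmp_path):
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    g = InteractionGraph({"A", "B"}, {("A", "B"): 3}, win)
    path = tmp_path / "g.graphml"
    export_graph(g, path, "graphml", roles={"A": "leader", "B": "regular"})
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"A", "B"}
    assert back.edges["A", "B"]["count"] == 3
    assert back.nodes["A"]["role"] == "leader"


def test_export_edge_csv_row_count(tmp_path):
    win = (datetime(2020, 1, 1), datetime(2020, 2, 1))
    g = InteractionGraph({"A", "B", "C"}, {("A", "B"): 3, ("B", "C"): 1}, win)
    path = tmp_path / "edges.csv"
    export_graph(g, path, "edge_csv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) - 1 == len(g.multi_edge_counts)
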