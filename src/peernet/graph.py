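"""Engagement tiers, dyadic interactions, interval graphs, density, cliques.

The community's events are stratified by engagement intensity: authored
content (posts, comments, polls) is *high* engagement, lightweight responses
(reactions, poll votes) are *medium*, and passive views — lurking — are
*low*.  Network structure is built only from the high/medium tiers: each
non-view child event yields one dyadic interaction between its actor and the
author of the parent content, and two members are adjacent in the interval
graph when at least one such interaction links them inside the window.
Views never influence any graph statistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

from .io_model import CommunityLog, EngagementError, EventKind

__all__ = [
    "EngagementTier",
    "DEFAULT_TIERS",
    "classify_tier",
    "DyadicInteraction",
    "derive_dyads",
    "InteractionGraph",
    "build_graph",
    "density",
    "maximal_cliques",
    "export_graph",
    "roles_at_end",
]


class EngagementTier(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


#: Default tier per event kind.  Polls are authored content and classed
#: high with posts; votes are reaction-like and classed medium.  Both are
#: overridable via the ``tiers`` argument of :func:`classify_tier` and
#: :func:`derive_dyads`.
DEFAULT_TIERS: Mapping[EventKind, EngagementTier] = {
    EventKind.POST: EngagementTier.HIGH,
    EventKind.COMMENT: EngagementTier.HIGH,
    EventKind.POLL: EngagementTier.HIGH,
    EventKind.REACTION: EngagementTier.MEDIUM,
    EventKind.VOTE: EngagementTier.MEDIUM,
    EventKind.VIEW: EngagementTier.LOW,
}


def classify_tier(
    kind: EventKind, tiers: Optional[Mapping[EventKind, EngagementTier]] = None
) -> EngagementTier:
    """Total classification of an event kind into an engagement tier."""
    return (tiers or DEFAULT_TIERS)[EventKind(kind)]


@dataclass(frozen=True)
class DyadicInteraction:
    """One pairwise tie: the actor of a child event and the author of its
    parent content.  ``member_a`` is the responding actor, ``member_b`` the
    parent author; graph construction treats the pair as unordered."""

    member_a: str
    member_b: str
    tier: EngagementTier
    timestamp: datetime
    source_event: str

    @property
    def pair(self) -> tuple:
        return (self.member_a, self.member_b) if self.member_a < self.member_b else (
            self.member_b,
            self.member_a,
        )


def derive_dyads(
    log: CommunityLog,
    tiers: Optional[Mapping[EventKind, EngagementTier]] = None,
) -> list:
    """One dyad per non-view child event, at the child event's tier.

    Root posts/polls yield no dyad of their own; self-replies and views
    yield nothing.  Low-tier kinds never produce dyads, so adding any number
    of view events to a log leaves the output unchanged.
    """
    tiers = tiers or DEFAULT_TIERS
    out: list = []
    for e in log.events:
        if e.parent_id is None:
            continue
        tier = tiers[e.kind]
        if tier is EngagementTier.LOW:
            continue
        parent = log.event(e.parent_id)
        if parent.actor_id == e.actor_id:
            continue
        out.append(
            DyadicInteraction(
                member_a=e.actor_id,
                member_b=parent.actor_id,
                tier=tier,
                timestamp=e.timestamp,
                source_event=e.event_id,
            )
        )
    return out


@dataclass
class InteractionGraph:
    """Undirected multigraph summary over a half-open time window.

    ``multi_edge_counts`` maps each unordered member pair (as a sorted
    2-tuple) to its interaction count; the simple-edge set is the pairs with
    count >= 1.
    """

    nodes: set
    multi_edge_counts: dict
    window: tuple  # (start, end) half-open datetimes

    def simple_edges(self) -> list:
        return list(self.multi_edge_counts)

    def to_networkx(self, roles: Optional[Mapping[str, str]] = None) -> nx.Graph:
        g = nx.Graph()
        for n in sorted(self.nodes):
            attrs = {"role": roles[n]} if roles and n in roles else {}
            g.add_node(n, **attrs)
        for (a, b), c in self.multi_edge_counts.items():
            g.add_edge(a, b, count=c)
        return g


def build_graph(
    dyads: Iterable[DyadicInteraction],
    window: tuple,
    members_present: set,
) -> InteractionGraph:
    """Aggregate dyads falling in ``[start, end)`` over a fixed node set."""
    start, end = window
    if not start < end:
        raise ValueError("window start must precede end")
    counts: dict = {}
    for d in dyads:
        if not (start <= d.timestamp < end):
            continue
        for m in (d.member_a, d.member_b):
            if m not in members_present:
                raise EngagementError(
                    f"dyad {d.source_event!r} references member {m!r} "
                    "outside members_present"
                )
        pair = d.pair
        counts[pair] = counts.get(pair, 0) + 1
    return InteractionGraph(nodes=set(members_present), multi_edge_counts=counts, window=window)


def density(graph: InteractionGraph) -> float:
    """Fraction of possible member pairs linked by >=1 medium/high
    interaction: ``|simple edges| / (n*(n-1)/2)``."""
    n = len(graph.nodes)
    if n < 2:
        raise EngagementError("density undefined for fewer than 2 nodes")
    return len(graph.multi_edge_counts) / (n * (n - 1) / 2)


def maximal_cliques(graph: InteractionGraph) -> list:
    """All maximal cliques of the simple-edge graph, as sorted node tuples,
    ordered by size descending then lexicographically.

    Uses pivoting Bron-Kerbosch enumeration (networkx ``find_cliques``);
    isolated nodes are singleton cliques.
    """
    g = graph.to_networkx()
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques, key=lambda c: (-len(c), c))


def export_graph(
    graph: InteractionGraph,
    path: str | Path,
    format: str = "graphml",
    roles: Optional[Mapping[str, str]] = None,
) -> None:
    """Write GraphML (node ``role`` attribute, edge ``count`` attribute) or
    an edge-list CSV (member_a, member_b, interaction_count)."""
    path = Path(path)
    try:
        if format == "graphml":
            nx.write_graphml(graph.to_networkx(roles), path)
        elif format == "edge_csv":
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(["member_a", "member_b", "interaction_count"])
                for (a, b), c in sorted(graph.multi_edge_counts.items()):
                    writer.writerow([a, b, c])
        else:
            raise ValueError(f"unknown format {format!r} (expected 'graphml' or 'edge_csv')")
    except OSError as exc:
        raise EngagementError(f"cannot write {path}: {exc}") from exc


def roles_at_end(log: CommunityLog) -> dict:
    """Convenience: member -> role-group label for graph exports."""
    return {m.member_id: m.role_group.value for m in log.members}
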