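"""The community's weighted interaction centrality and its relative form.

For each member and each stable period, raw centrality is a weighted sum of
two activity measures over the member's high/medium-engagement dyadic
interactions inside the period:

    raw = 0.8 * n_interactions + 0.2 * n_partners

where ``n_interactions`` counts interaction events involving the member
(multi-edge degree) and ``n_partners`` counts distinct other members so
connected (simple degree).  The two terms are deliberately distinct: the
first rewards volume of exchange, the second breadth of reach.  Dividing by
the period's maximum raw value gives *relative centrality* in [0, 1]; in a
period with no interactions at all, every member's relative centrality is
defined as 0.

Per-member means across periods respect role eligibility: a designated
leader is scored only over periods during which a leader role interval was
in force, a regular member over periods overlapping their membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_model import CommunityLog, Member, Role
from .graph import DyadicInteraction
from .segmentation import StablePeriod

__all__ = [
    "CentralityWeights",
    "CentralityScore",
    "MemberCentralitySummary",
    "period_centrality",
    "member_mean_relative",
    "group_summary",
    "centrality_pipeline",
]


@dataclass(frozen=True)
class CentralityWeights:
    """Mixing weights for interaction volume vs partner breadth."""

    w_connections: float = 0.8
    w_partners: float = 0.2

    def __post_init__(self) -> None:
        if self.w_connections < 0 or self.w_partners < 0:
            raise ValueError("centrality weights must be non-negative")
        if not math.isclose(self.w_connections + self.w_partners, 1.0, abs_tol=1e-9):
            raise ValueError("centrality weights must sum to 1")


@dataclass(frozen=True)
class CentralityScore:
    member_id: str
    period_index: int
    n_interactions: int
    n_partners: int
    raw: float
    relative: float


@dataclass(frozen=True)
class MemberCentralitySummary:
    member_id: str
    role_group: Role
    mean_relative: float
    sd_relative: float
    n_periods: int
    single_period: bool = False
    no_eligible_periods: bool = False


def period_centrality(
    dyads: Iterable[DyadicInteraction],
    members: set,
    weights: CentralityWeights = CentralityWeights(),
    period_index: int = 0,
) -> list:
    """Score every member present in a period, zeros included.

    ``dyads`` must already be restricted to the period.  Ties at the period
    maximum all receive relative centrality 1.0; an interaction-free period
    yields all zeros.
    """
    if not members:
        raise ValueError("empty member set")
    inter = {m: 0 for m in members}
    partners = {m: set() for m in members}
    for d in dyads:
        for me, other in ((d.member_a, d.member_b), (d.member_b, d.member_a)):
            if me in inter:
                inter[me] += 1
                partners[me].add(other)
    raw = {
        m: weights.w_connections * inter[m] + weights.w_partners * len(partners[m])
        for m in members
    }
    top = max(raw.values())
    out = []
    for m in sorted(members):
        rel = raw[m] / top if top > 0 else 0.0
        out.append(
            CentralityScore(
                member_id=m,
                period_index=period_index,
                n_interactions=inter[m],
                n_partners=len(partners[m]),
                raw=raw[m],
                relative=rel,
            )
        )
    return out


def _eligible(member: Member, period: StablePeriod) -> bool:
    if member.role_group is Role.LEADER:
        # role intervals are half-open: the role is held on [start, end)
        return any(
            iv.role is Role.LEADER
            and iv.start < period.end
            and (iv.end is None or iv.end > period.start)
            for iv in member.role_history
        )
    # membership is inclusive of the exit date
    return member.join_date < period.end and (
        member.exit_date is None or member.exit_date >= period.start
    )


def member_mean_relative(
    scores: Iterable[CentralityScore],
    members: Sequence[Member],
    periods: Sequence[StablePeriod],
    *,
    exclude_admins: bool = True,
) -> list:
    """Per-member mean and SD of relative centrality over eligible periods.

    Leaders are scored only over periods during which they held the leader
    role; everyone else over periods overlapping their membership.  Sample
    SD (ddof=1); a member scored in exactly one period gets SD 0 with a
    ``single_period`` flag, and a member with no eligible scored period is
    flagged ``no_eligible_periods`` rather than dropped.
    """
    by_member: dict = {}
    for s in scores:
        by_member.setdefault(s.member_id, {})[s.period_index] = s
    period_by_index = {p.index: p for p in periods}

    out = []
    for m in members:
        if exclude_admins and m.is_admin:
            continue
        vals = []
        for idx, s in sorted(by_member.get(m.member_id, {}).items()):
            p = period_by_index.get(idx)
            if p is not None and _eligible(m, p):
                vals.append(s.relative)
        if not vals:
            out.append(
                MemberCentralitySummary(
                    member_id=m.member_id,
                    role_group=m.role_group,
                    mean_relative=float("nan"),
                    sd_relative=float("nan"),
                    n_periods=0,
                    no_eligible_periods=True,
                )
            )
            continue
        mean = sum(vals) / len(vals)
        if len(vals) == 1:
            sd, single = 0.0, True
        else:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            single = False
        out.append(
            MemberCentralitySummary(
                member_id=m.member_id,
                role_group=m.role_group,
                mean_relative=mean,
                sd_relative=sd,
                n_periods=len(vals),
                single_period=single,
            )
        )
    return out


class EmptyGroupError(ValueError):
    pass


def group_summary(summaries: Iterable[MemberCentralitySummary]) -> dict:
    """Group mean/SD/n of per-member mean relative centrality, for leaders
    and regular members.  Raises :class:`EmptyGroupError` if either group
    has no scored member."""
    groups = {Role.LEADER: [], Role.REGULAR: []}
    for s in summaries:
        if s.no_eligible_periods:
            continue
        if s.role_group in groups:
            groups[s.role_group].append(s.mean_relative)
    out = {}
    for role, vals in groups.items():
        if not vals:
            raise EmptyGroupError(f"no scored members in group {role.value!r}")
        mean = sum(vals) / len(vals)
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            if len(vals) > 1
            else 0.0
        )
        out[role.value] = {"mean": mean, "sd": sd, "n": len(vals)}
    return out


def centrality_pipeline(
    log: CommunityLog,
    dyads: Sequence[DyadicInteraction],
    periods: Sequence[StablePeriod],
    weights: CentralityWeights = CentralityWeights(),
    *,
    exclude_admins_from_scores: bool = True,
) -> tuple:
    """Score every period, then summarise per member.

    Returns ``(scores, summaries)``.  Admin accounts are excluded from the
    per-period member sets by default so they never define the period
    maximum used for normalization of the leader/regular comparison.
    """
    scores: list = []
    for p in periods:
        present = set(p.member_ids)
        if exclude_admins_from_scores:
            admins = {m.member_id for m in log.members if m.is_admin}
            present -= admins
        if not present:
            continue
        start, end = p.window
        in_period = [d for d in dyads if start <= d.timestamp < end
                     and d.member_a in present and d.member_b in present]
        scores.extend(period_centrality(in_period, present, weights, period_index=p.index))
    summaries = member_mean_relative(scores, log.members, periods)
    return scores, summaries
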