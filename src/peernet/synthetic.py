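"""Synthetic peer-support communities with known ground truth.

Two generators:

:func:`simulate_community`
    An agent-based event-log simulator emulating a moderated peer-support
    community of ~10 designated leaders and ~200 regular members over ~33
    months: Poisson member arrival, leader activity roughly an order of
    magnitude above regular members, heavy lurking (~85% of events are
    views), and a low exit rate (~12% over the window).  Returns the log
    together with the ground truth (who the true leaders are and their
    configured activity multiplier), for recovery tests.

:func:`fixture_from_margins`
    A deterministic log whose event-kind counts, member count,
    connected-member count, and exit count equal requested margins exactly
    — used to pin descriptive statistics to known totals.

Engagement draws are independent Bernoulli per (member, content-item) pair:
the simplest process consistent with heavy-lurking aggregate margins.  No
preferential attachment is modelled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from datetime import date, datetime, time, timedelta
from typing import Mapping

import numpy as np

from .io_model import (
    AgeBand,
    CommunicationEvent,
    CommunityLog,
    CodeAssignment,
    EventKind,
    InsulinModality,
    Member,
    Role,
    RoleInterval,
    SexInferred,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_community",
    "fixture_from_margins",
    "code_assignments_from_margins",
    "EXAMPLE_EVENT_MARGINS",
    "EXAMPLE_CODE_MARGINS",
]

#: Event margins of a 33-month, 222-member type 1 diabetes peer-support
#: community (10 designated leaders; 203 members ever connected; 26 exits).
EXAMPLE_EVENT_MARGINS = {
    EventKind.POST: 1096,
    EventKind.COMMENT: 3998,
    EventKind.REACTION: 5835,
    EventKind.POLL: 15,
    EventKind.VOTE: 398,
    EventKind.VIEW: 63709,
}

#: Code-application margins for the same community: support categories
#: (informational, esteem-related, emotional, network, tangible), direction
#: split of support codes, and non-support codes.
EXAMPLE_CODE_MARGINS = {
    "informational": 2277,
    "esteem_related": 699,
    "emotional": 275,
    "network": 100,
    "tangible": 79,
    "nonsupport": 2823,
    "providing_support": 2303,
    "seeking_support": 1127,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults are calibrated to the community scale described above.

    ``base_post_rate`` is posts per active regular member per month;
    leaders author and comment at ``leader_activity_multiplier`` times the
    regular rate and react at ``leader_reaction_multiplier`` times.
    ``member_arrival_rate`` is the Poisson mean of new regular members per
    month; ``exit_hazard`` the per-member per-month exit probability.
    """

    months: int = 33
    n_leaders: int = 10
    n_admins: int = 0
    member_arrival_rate: float = 6.4
    leader_activity_multiplier: float = 10.0
    leader_reaction_multiplier: float = 3.0
    base_post_rate: float = 0.15
    comment_prob: float = 0.02
    reaction_prob: float = 0.04
    view_prob: float = 0.5
    poll_rate: float = 0.45
    votes_per_poll_mean: float = 27.0
    exit_hazard: float = 0.004
    start: date = date(2017, 6, 21)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("comment_prob", "reaction_prob", "view_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.exit_hazard <= 1.0:
            raise ValueError("exit_hazard must be in [0, 1]")
        for name in (
            "member_arrival_rate",
            "base_post_rate",
            "poll_rate",
            "votes_per_poll_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.leader_activity_multiplier < 1 or self.leader_reaction_multiplier < 1:
            raise ValueError("leader multipliers must be >= 1")
        if self.months < 1 or self.n_leaders < 0 or self.n_admins < 0:
            raise ValueError("months >= 1, counts >= 0 required")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start"] = self.start.isoformat()
        return d


@dataclass
class GroundTruth:
    true_leader_ids: frozenset
    configured_leader_effect: float
    activity_rates: dict  # member_id -> latent posts-per-month rate


def _month_starts(start: date, months: int) -> list:
    out = [start]
    cur = start
    for _ in range(months):
        y, m = cur.year, cur.month + 1
        if m == 13:
            y, m = y + 1, 1
        cur = date(y, m, min(start.day, 28))
        out.append(cur)
    return out


def simulate_community(config: SimulationConfig) -> tuple:
    """Generate a validated :class:`CommunityLog` plus its ground truth.

    Month by month: new regular members arrive (Poisson), each active
    member authors posts (Poisson at their latent rate), leaders
    occasionally open polls, and every authored item accrues comments,
    reactions, votes, and views from the members active that month by
    independent Bernoulli draws.  Exits follow a per-month hazard.  One
    sub-stream of randomness per month keeps regeneration stable under the
    same seed.
    """
    config.validate()
    month_bounds = _month_starts(config.start, config.months)
    obs_start = month_bounds[0]
    obs_end = month_bounds[-1] - timedelta(days=1)

    root = np.random.SeedSequence(config.seed)
    month_seeds = root.spawn(config.months)
    demo_rng = np.random.default_rng(root.spawn(2)[1])

    sex_levels_init = [s.value for s in SexInferred]
    sex_p_init = np.array([0.70, 0.25, 0.045, 0.005])
    sex_p_init = sex_p_init / sex_p_init.sum()

    members: list = []
    leader_ids = [f"l{i + 1:02d}" for i in range(config.n_leaders)]
    admin_ids = [f"a{i + 1:02d}" for i in range(config.n_admins)]
    for lid in leader_ids:
        # sex is name-inferred for everyone; age band and insulin modality
        # are unqueried for leaders and stay missing
        members.append(
            Member(
                member_id=lid,
                join_date=obs_start,
                role_history=(RoleInterval(Role.LEADER, obs_start),),
                sex_inferred=SexInferred(demo_rng.choice(sex_levels_init, p=sex_p_init)),
            )
        )
    for aid in admin_ids:
        members.append(
            Member(
                member_id=aid,
                join_date=obs_start,
                role_history=(RoleInterval(Role.ADMIN, obs_start),),
            )
        )

    events: list = []
    eid = 0

    def new_event(actor, kind, ts, parent=None):
        nonlocal eid
        eid += 1
        ev = CommunicationEvent(
            event_id=f"e{eid:07d}", actor_id=actor, kind=kind, timestamp=ts, parent_id=parent
        )
        events.append(ev)
        return ev

    active: dict = {m.member_id: m for m in members if not m.is_admin}
    exited: dict = {}
    reg_count = 0
    rates = {lid: config.base_post_rate * config.leader_activity_multiplier for lid in leader_ids}

    sex_levels = np.array([s.value for s in SexInferred])
    sex_p = np.array([0.70, 0.25, 0.045, 0.005])
    sex_p = sex_p / sex_p.sum()
    age_levels = np.array([a.value for a in AgeBand])
    age_p = np.array([0.665, 0.02, 0.098, 0.217])
    age_p = age_p / age_p.sum()
    mod_levels = np.array([m.value for m in InsulinModality])
    mod_p = np.array([0.528, 0.264, 0.208])

    for mi in range(config.months):
        rng = np.random.default_rng(month_seeds[mi])
        m_start, m_end = month_bounds[mi], month_bounds[mi + 1]
        span_days = (m_end - m_start).days

        # arrivals
        n_new = int(rng.poisson(config.member_arrival_rate))
        for _ in range(n_new):
            reg_count += 1
            mid = f"m{reg_count:04d}"
            jd = m_start + timedelta(days=int(rng.integers(0, span_days)))
            mem = Member(
                member_id=mid,
                join_date=jd,
                role_history=(RoleInterval(Role.REGULAR, jd),),
                sex_inferred=SexInferred(rng.choice(sex_levels, p=sex_p)),
                age_at_diagnosis_band=AgeBand(rng.choice(age_levels, p=age_p)),
                insulin_modality=InsulinModality(rng.choice(mod_levels, p=mod_p)),
            )
            members.append(mem)
            active[mid] = mem
            rates[mid] = config.base_post_rate

        ids = sorted(active)
        is_leader = np.array([i in set(leader_ids) for i in ids])
        n_active = len(ids)

        # authored content for the month
        items: list = []  # (author, kind)
        for i in ids:
            mult = config.leader_activity_multiplier if i in rates and i in set(leader_ids) else 1.0
            n_posts = int(rng.poisson(config.base_post_rate * mult))
            items.extend((i, EventKind.POST) for _ in range(n_posts))
        n_polls = int(rng.poisson(config.poll_rate)) if leader_ids else 0
        for _ in range(n_polls):
            items.append((str(rng.choice(leader_ids)), EventKind.POLL))
        rng.shuffle(items)

        c_prob = np.where(
            is_leader,
            np.minimum(config.comment_prob * config.leader_activity_multiplier, 1.0),
            config.comment_prob,
        )
        r_prob = np.where(
            is_leader,
            np.minimum(config.reaction_prob * config.leader_reaction_multiplier, 1.0),
            config.reaction_prob,
        )

        # second-resolution grid keeps child timestamps >= parent's
        n_items = max(len(items), 1)
        step = span_days * 86_400 // (n_items + 1)
        for k, (author, kind) in enumerate(items):
            ts0 = datetime.combine(m_start, time.min) + timedelta(seconds=(k + 1) * step)
            parent = new_event(author, kind, ts0)
            others = [j for j in range(n_active) if ids[j] != author]
            if not others:
                continue
            oidx = np.array(others)
            u = rng.random((3, len(oidx)))
            commenters = oidx[u[0] < c_prob[oidx]] if kind is EventKind.POST else np.array([], dtype=int)
            reactors = oidx[u[1] < r_prob[oidx]] if kind is EventKind.POST else np.array([], dtype=int)
            viewers = oidx[u[2] < config.view_prob]
            child_ts = ts0 + timedelta(seconds=1)
            comment_events = []
            for j in commenters:
                comment_events.append(
                    new_event(ids[j], EventKind.COMMENT, child_ts, parent.event_id)
                )
            for j in reactors:
                # most reactions target the post; some a comment beneath it
                if comment_events and rng.random() < 0.3:
                    target = comment_events[int(rng.integers(len(comment_events)))]
                    new_event(ids[j], EventKind.REACTION, child_ts + timedelta(seconds=1), target.event_id)
                else:
                    new_event(ids[j], EventKind.REACTION, child_ts, parent.event_id)
            if kind is EventKind.POLL:
                p_vote = min(config.votes_per_poll_mean / len(oidx), 1.0)
                voters = oidx[rng.random(len(oidx)) < p_vote]
                for j in voters:
                    new_event(ids[j], EventKind.VOTE, child_ts, parent.event_id)
            for j in viewers:
                new_event(ids[j], EventKind.VIEW, child_ts, parent.event_id)

        # exits at month end (never in the join month, so role intervals
        # keep positive length)
        for i in list(active):
            if active[i].join_date >= m_start:
                continue
            if rng.random() < config.exit_hazard:
                mem = active.pop(i)
                exited[i] = m_end - timedelta(days=1)
                rates.pop(i, None)

    # write exit dates / close role intervals
    final_members = []
    for m in members:
        if m.member_id in exited:
            ed = exited[m.member_id]
            ivs = tuple(
                RoleInterval(iv.role, iv.start, ed if iv.end is None else iv.end)
                for iv in m.role_history
            )
            m = Member(
                member_id=m.member_id,
                join_date=m.join_date,
                role_history=ivs,
                exit_date=ed,
                sex_inferred=m.sex_inferred,
                age_at_diagnosis_band=m.age_at_diagnosis_band,
                region=m.region,
                insulin_modality=m.insulin_modality,
            )
        final_members.append(m)

    log = CommunityLog(
        members=final_members,
        events=events,
        observation_start=obs_start,
        observation_end=obs_end,
    ).validate()
    truth = GroundTruth(
        true_leader_ids=frozenset(leader_ids),
        configured_leader_effect=config.leader_activity_multiplier,
        activity_rates=dict(rates),
    )
    return log, truth


class InfeasibleMarginsError(ValueError):
    pass


def fixture_from_margins(
    counts: Mapping[EventKind, int],
    n_members: int,
    n_connected: int,
    n_exited: int,
    seed: int = 0,
    *,
    n_leaders: int = 0,
    start: date = date(2017, 6, 21),
    months: int = 33,
) -> CommunityLog:
    """Deterministic log hitting the requested margins exactly.

    Construction is hub-and-spokes: member 1 (the hub) authors every post
    and poll; each of the remaining connected members contributes one child
    event on hub content (comment, then reaction, then vote as supplies
    allow); leftover child events are recycled among already-connected
    members; views are spread round-robin over the whole roster and create
    no ties.  The last ``n_exited`` members receive exit dates.
    """
    counts = {EventKind(k): int(v) for k, v in counts.items()}
    for k in EventKind:
        counts.setdefault(k, 0)
    n_posts, n_comments = counts[EventKind.POST], counts[EventKind.COMMENT]
    n_reactions, n_polls = counts[EventKind.REACTION], counts[EventKind.POLL]
    n_votes, n_views = counts[EventKind.VOTE], counts[EventKind.VIEW]

    if n_members < 1:
        raise InfeasibleMarginsError("need at least one member")
    if n_connected > n_members:
        raise InfeasibleMarginsError("n_connected exceeds n_members")
    if n_connected == 1:
        raise InfeasibleMarginsError("a single connected member is impossible: ties are pairwise")
    if n_exited > n_members:
        raise InfeasibleMarginsError("n_exited exceeds n_members")
    if n_comments > 0 and n_posts == 0:
        raise InfeasibleMarginsError("comments require at least one post")
    if n_reactions > 0 and n_posts == 0 and n_comments == 0:
        raise InfeasibleMarginsError("reactions require a post or comment")
    if n_votes > 0 and n_polls == 0:
        raise InfeasibleMarginsError("votes require at least one poll")
    if n_views > 0 and n_posts == 0 and n_polls == 0:
        raise InfeasibleMarginsError("views require a post or poll")
    n_children = n_comments + n_reactions + n_votes
    if n_connected == 0 and n_children > 0 and n_members < 1:
        raise InfeasibleMarginsError("child events need an author")
    if n_connected > 0 and n_children < n_connected - 1:
        raise InfeasibleMarginsError(
            f"{n_connected} connected members need >= {n_connected - 1} child events"
        )
    if n_connected > 0 and n_children > 0 and n_posts + n_polls == 0:
        raise InfeasibleMarginsError("connected members need parent content")

    month_bounds = _month_starts(start, months)
    obs_start, obs_end = month_bounds[0], month_bounds[-1] - timedelta(days=1)
    span_days = (obs_end - obs_start).days

    # roster: joins spread evenly; hub + leaders join at the start
    member_ids = [f"m{i + 1:04d}" for i in range(n_members)]
    join_dates = {}
    for i, mid in enumerate(member_ids):
        if i < max(n_leaders, 1):
            join_dates[mid] = obs_start
        else:
            frac = i / max(n_members - 1, 1)
            join_dates[mid] = obs_start + timedelta(days=int(frac * span_days * 0.8))
    exit_ids = set(member_ids[n_members - n_exited :]) if n_exited else set()

    members = []
    for i, mid in enumerate(member_ids):
        jd = join_dates[mid]
        ed = obs_end - timedelta(days=1) if mid in exit_ids else None
        if ed is not None and ed <= jd:
            ed = min(jd + timedelta(days=1), obs_end)
        role = Role.LEADER if i < n_leaders else Role.REGULAR
        members.append(
            Member(
                member_id=mid,
                join_date=jd,
                role_history=(RoleInterval(role, jd, ed),),
                exit_date=ed,
            )
        )

    hub = member_ids[0]
    events: list = []
    eid = 0

    def new_event(actor, kind, ts, parent=None):
        nonlocal eid
        eid += 1
        ev = CommunicationEvent(
            event_id=f"e{eid:07d}", actor_id=actor, kind=kind, timestamp=ts, parent_id=parent
        )
        events.append(ev)
        return ev

    # roots: spread over the window so monthly series are non-degenerate
    t0 = datetime.combine(obs_start, time.min)
    total_roots = n_posts + n_polls
    root_step = max((span_days * 86_400 - 7_200) // max(total_roots, 1), 1)
    posts, polls = [], []
    for r in range(total_roots):
        ts = t0 + timedelta(seconds=r * root_step)
        if r < n_posts:
            posts.append(new_event(hub, EventKind.POST, ts))
        else:
            polls.append(new_event(hub, EventKind.POLL, ts))

    # spokes: one child event each to pin the connected count exactly
    connected_ids = member_ids[:n_connected]
    spokes = connected_ids[1:] if n_connected >= 2 else []
    budget = {"comment": n_comments, "reaction": n_reactions, "vote": n_votes}
    si = 0
    for mid in spokes:
        if budget["comment"] > 0 and posts:
            parent = posts[si % len(posts)]
            new_event(mid, EventKind.COMMENT, parent.timestamp + timedelta(seconds=1), parent.event_id)
            budget["comment"] -= 1
        elif budget["reaction"] > 0 and posts:
            parent = posts[si % len(posts)]
            new_event(mid, EventKind.REACTION, parent.timestamp + timedelta(seconds=1), parent.event_id)
            budget["reaction"] -= 1
        elif budget["vote"] > 0 and polls:
            parent = polls[si % len(polls)]
            new_event(mid, EventKind.VOTE, parent.timestamp + timedelta(seconds=1), parent.event_id)
            budget["vote"] -= 1
        else:
            raise InfeasibleMarginsError("ran out of child events for connected members")
        si += 1

    # leftovers recycled among already-connected members (or self-authored
    # by the hub when no ties are allowed)
    def filler_actor(parent_author: str, offset: int) -> str:
        if n_connected >= 2:
            pool = [m for m in connected_ids if m != parent_author]
            return pool[offset % len(pool)]
        return parent_author  # self-children carry no tie

    for j in range(budget["comment"]):
        parent = posts[j % len(posts)]
        new_event(
            filler_actor(parent.actor_id, j),
            EventKind.COMMENT,
            parent.timestamp + timedelta(seconds=2),
            parent.event_id,
        )
    for j in range(budget["reaction"]):
        parent = posts[j % len(posts)] if posts else None
        if parent is None:
            raise InfeasibleMarginsError("reactions require a post")
        new_event(
            filler_actor(parent.actor_id, j + 1),
            EventKind.REACTION,
            parent.timestamp + timedelta(seconds=2),
            parent.event_id,
        )
    for j in range(budget["vote"]):
        parent = polls[j % len(polls)]
        new_event(
            filler_actor(parent.actor_id, j),
            EventKind.VOTE,
            parent.timestamp + timedelta(seconds=2),
            parent.event_id,
        )

    roots = posts + polls
    for j in range(n_views):
        parent = roots[j % len(roots)]
        viewer = member_ids[j % n_members]
        new_event(viewer, EventKind.VIEW, parent.timestamp + timedelta(seconds=3), parent.event_id)

    log = CommunityLog(
        members=members,
        events=events,
        observation_start=obs_start,
        observation_end=obs_end,
    ).validate()
    return log


def code_assignments_from_margins(
    margins: Mapping[str, int] = EXAMPLE_CODE_MARGINS,
    *,
    event_prefix: str = "c",
) -> list:
    """Synthetic code-assignment list hitting category/direction margins.

    One code per assignment.  Category counts are assigned to that
    category's first third-level code (the margins constrain categories,
    not third-level splits); the direction split is laid over the support
    codes in order; non-support applications are tagged "socializing" with
    direction "neither".  Event ids are synthetic placeholders.
    """
    from .content_codes import DEFAULT_TAXONOMY

    cat_counts = {
        c: int(margins.get(c, 0)) for c in DEFAULT_TAXONOMY.categories
    }
    n_support = sum(cat_counts.values())
    n_prov = int(margins.get("providing_support", 0))
    n_seek = int(margins.get("seeking_support", 0))
    if n_prov + n_seek != n_support:
        raise InfeasibleMarginsError(
            "direction counts must sum to the support-category total"
        )
    out: list = []
    i = 0
    k = 0  # support applications placed so far, for the direction split
    for cat, n in cat_counts.items():
        code = DEFAULT_TAXONOMY.third_level[cat][0]
        for _ in range(n):
            direction = "providing_support" if k < n_prov else "seeking_support"
            i += 1
            k += 1
            out.append(CodeAssignment(f"{event_prefix}{i:05d}", (code,), direction))
    for _ in range(int(margins.get("nonsupport", 0))):
        i += 1
        out.append(CodeAssignment(f"{event_prefix}{i:05d}", ("socializing",), "neither"))
    return out
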