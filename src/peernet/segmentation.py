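"""Monthly membership growth and Poisson-thresholded stable periods.

Membership in a growing community is non-stationary, so per-window network
statistics are computed over *stable membership periods*: the observation
window is cut at the start of every calendar month whose new-member count
reaches a growth threshold.  The threshold itself is derived from a Poisson
model of member arrival — the mean monthly arrival count is taken as the
Poisson mean λ, and the threshold is the smallest count that is "unusually
large" under that model.

Two literal readings of "the lowest number of new members for which there
was a <50% probability of occurrence" are supported:

``P_ge_k_lt_half``
    smallest k with P(X >= k) < 0.5 (the default);
``P_gt_k_lt_half``
    smallest k with P(X > k) < 0.5 (equivalently the Poisson median).

At λ = 212/33 ≈ 6.42 — ~212 regular members arriving over a 33-month
window — the first rule gives 7 and the second gives 6.  The threshold can
also be fixed directly (``k=6``) to bypass the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

from scipy import stats

from .io_model import CommunityLog, Member

__all__ = [
    "MonthlyGrowth",
    "StablePeriod",
    "monthly_growth",
    "growth_threshold",
    "stable_periods",
    "TAIL_RULES",
]

TAIL_RULES = ("P_ge_k_lt_half", "P_gt_k_lt_half")


@dataclass(frozen=True)
class MonthlyGrowth:
    month: date  # first day of the calendar month
    new_members: int
    exits: int
    cumulative_members: int


@dataclass(frozen=True)
class StablePeriod:
    index: int
    start: date
    end: date  # exclusive (next period's start, or day after observation_end)
    member_ids: frozenset

    @property
    def window(self) -> tuple:
        """Half-open datetime window for event filtering."""
        return (
            datetime.combine(self.start, time.min),
            datetime.combine(self.end, time.min),
        )


def _month_start(d: date) -> date:
    return d.replace(day=1)


def _next_month(d: date) -> date:
    return date(d.year + 1, 1, 1) if d.month == 12 else date(d.year, d.month + 1, 1)


def _counted(m: Member, include_leaders: bool, include_admins: bool) -> bool:
    if m.is_admin:
        return include_admins
    if m.is_ever_leader:
        return include_leaders
    return True


def monthly_growth(
    log: CommunityLog,
    *,
    include_leaders: bool = True,
    include_admins: bool = False,
) -> list:
    """One record per calendar month of the observation window.

    Counts are derived from join and exit dates.  By default all non-admin
    joins count as "new members" (leaders included); both flags are
    configurable because λ for the growth threshold is usually estimated
    from this series.
    """
    months: list = []
    m = _month_start(log.observation_start)
    end_month = _month_start(log.observation_end)
    while m <= end_month:
        months.append(m)
        m = _next_month(m)

    joins = {mo: 0 for mo in months}
    exits = {mo: 0 for mo in months}
    for mem in log.members:
        if not _counted(mem, include_leaders, include_admins):
            continue
        jm = _month_start(mem.join_date)
        if jm in joins:
            joins[jm] += 1
        if mem.exit_date is not None:
            em = _month_start(mem.exit_date)
            if em in exits:
                exits[em] += 1

    out: list = []
    cum = 0
    for mo in months:
        cum += joins[mo] - exits[mo]
        out.append(
            MonthlyGrowth(
                month=mo, new_members=joins[mo], exits=exits[mo], cumulative_members=cum
            )
        )
    return out


def mean_arrival_rate(growth: Sequence[MonthlyGrowth]) -> float:
    """Mean monthly new-member count — the λ fed to the threshold rule."""
    if not growth:
        raise ValueError("empty growth sequence")
    return sum(g.new_members for g in growth) / len(growth)


def growth_threshold(lambda_mean: float, tail_rule: str = "P_ge_k_lt_half") -> int:
    """Smallest integer count "unusual" under Poisson(λ), by direct pmf
    summation.

    Under ``P_ge_k_lt_half``: smallest k with P(X >= k) < 0.5, i.e. the
    smallest k whose lower tail P(X <= k-1) exceeds 0.5.  Under
    ``P_gt_k_lt_half``: smallest k with P(X > k) < 0.5.
    """
    if not lambda_mean > 0:
        raise ValueError("lambda_mean must be positive")
    if tail_rule not in TAIL_RULES:
        raise ValueError(f"unknown tail rule {tail_rule!r}; expected one of {TAIL_RULES}")
    cum = 0.0
    k = 0
    # accumulate pmf(0), pmf(1), ... until the relevant tail drops below 1/2
    while True:
        cum += float(stats.poisson.pmf(k, lambda_mean))
        # after adding pmf(k): cum = P(X <= k)
        if tail_rule == "P_ge_k_lt_half":
            # P(X >= k+1) = 1 - cum
            if 1.0 - cum < 0.5:
                return k + 1
        else:
            # P(X > k) = 1 - cum
            if 1.0 - cum < 0.5:
                return k
        k += 1
        if k > 10_000:  # unreachable for sane λ; guards vs fp pathology
            raise RuntimeError("threshold search failed to converge")


def _active_in(m: Member, start: date, end: date) -> bool:
    """Membership interval [join, exit] overlaps the half-open [start, end)."""
    if m.join_date >= end:
        return False
    return m.exit_date is None or m.exit_date >= start


def stable_periods(
    growth: Sequence[MonthlyGrowth],
    k: int,
    log: CommunityLog,
    *,
    include_admins: bool = True,
) -> list:
    """Cut the observation window at every month whose new-member count
    reaches ``k``; periods are contiguous, non-overlapping, and cover the
    window exactly.

    The first period always begins at ``observation_start``; a threshold
    month that contains it opens no extra boundary.  ``member_ids`` holds
    every member active at any point in the period (admins included by
    default so they can appear in graphs; exclude downstream as needed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    start = log.observation_start
    end_exclusive = log.observation_end + timedelta(days=1)
    boundaries = [start]
    for g in growth:
        if g.new_members >= k and start < g.month < end_exclusive:
            boundaries.append(g.month)
    boundaries = sorted(set(boundaries))

    out: list = []
    for i, b in enumerate(boundaries):
        e = boundaries[i + 1] if i + 1 < len(boundaries) else end_exclusive
        ids = frozenset(
            m.member_id
            for m in log.members
            if (include_admins or not m.is_admin) and _active_in(m, b, e)
        )
        out.append(StablePeriod(index=i, start=b, end=e, member_ids=ids))
    return out


def periods_to_rows(periods: Iterable[StablePeriod], growth: Sequence[MonthlyGrowth]) -> list:
    """Rows for periods.csv: index, start, end, n_members, n_new_members."""
    rows = []
    for p in periods:
        n_new = sum(g.new_members for g in growth if p.start <= g.month < p.end)
        rows.append(
            {
                "index": p.index,
                "start": p.start.isoformat(),
                "end": p.end.isoformat(),
                "n_members": len(p.member_ids),
                "n_new_members": n_new,
            }
        )
    return rows
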