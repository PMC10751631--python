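"""Descriptive surface of a community log: communication mix, engagement
ratios, retention, connectivity, and the compiled report.

All percentages use half-up rounding at the precision conventionally
printed (2 decimals for the communication-type breakdown, 1 decimal for
retention and connectivity); engagement ratios are expressed "to 1" against
authored items (posts + polls), which is the denominator consistent with
per-month authored-content framing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, time
from pathlib import Path
from typing import Optional

from .content_codes import round_half_up
from .graph import build_graph, density, derive_dyads
from .io_model import CommunityLog, EventKind
from .segmentation import _month_start, _next_month

__all__ = [
    "CommunicationBreakdown",
    "EngagementRatios",
    "breakdown",
    "ratios",
    "retention",
    "connectivity",
    "demographics",
    "monthly_density",
    "compile_report",
    "render_markdown",
]


@dataclass
class CommunicationBreakdown:
    counts: dict  # EventKind value -> count
    total: int
    percentages: dict  # EventKind value -> percent (2 decimals) or None


@dataclass
class EngagementRatios:
    comments_per_authored: Optional[float]
    reactions_per_authored: Optional[float]
    views_per_authored: Optional[int]
    votes_per_poll: Optional[int]
    n_authored: int
    n_polls: int


def breakdown(log: CommunityLog) -> CommunicationBreakdown:
    counts = {k.value: 0 for k in EventKind}
    for e in log.events:
        counts[e.kind.value] += 1
    total = len(log.events)
    if total == 0:
        pct = {k: None for k in counts}
    else:
        pct = {k: round_half_up(100.0 * v / total, 2) for k, v in counts.items()}
    return CommunicationBreakdown(counts=counts, total=total, percentages=pct)


def ratios(bd: CommunicationBreakdown) -> EngagementRatios:
    """Comments/reactions/views per authored item (posts + polls, to one
    decimal resp. nearest integer) and votes per poll.  Zero denominators
    leave the affected ratio None."""
    authored = bd.counts["post"] + bd.counts["poll"]
    polls = bd.counts["poll"]
    per = lambda n: None if authored == 0 else round_half_up(n / authored, 1)
    per_int = lambda n: None if authored == 0 else int(round_half_up(n / authored, 0))
    return EngagementRatios(
        comments_per_authored=per(bd.counts["comment"]),
        reactions_per_authored=per(bd.counts["reaction"]),
        views_per_authored=per_int(bd.counts["view"]),
        votes_per_poll=None if polls == 0 else int(round_half_up(bd.counts["vote"] / polls, 0)),
        n_authored=authored,
        n_polls=polls,
    )


def retention(log: CommunityLog) -> dict:
    """Joined / remaining / exited counts over non-admin members, with the
    exit percentage at one decimal."""
    members = log.non_admin_members()
    joined = len(members)
    exited = sum(
        1
        for m in members
        if m.exit_date is not None and m.exit_date <= log.observation_end
    )
    return {
        "joined": joined,
        "remaining": joined - exited,
        "exited": exited,
        "exit_percent": None if joined == 0 else round_half_up(100.0 * exited / joined, 1),
    }


def connectivity(log: CommunityLog, dyads=None) -> dict:
    """Members touched by at least one medium/high-engagement interaction
    over the full window, as a share of all non-admin members."""
    if dyads is None:
        dyads = derive_dyads(log)
    non_admin = {m.member_id for m in log.non_admin_members()}
    connected = set()
    for d in dyads:
        connected.add(d.member_a)
        connected.add(d.member_b)
    connected &= non_admin
    total = len(non_admin)
    return {
        "connected": len(connected),
        "total": total,
        "percent": None if total == 0 else round_half_up(100.0 * len(connected) / total, 1),
    }


def demographics(log: CommunityLog) -> dict:
    """Frequency tables over roster fields (non-admin members)."""
    members = log.non_admin_members()
    n = len(members)

    def table(getter) -> dict:
        counts: dict = {}
        for m in members:
            key = getter(m)
            counts[key] = counts.get(key, 0) + 1
        return {
            k: {"n": v, "percent": None if n == 0 else round_half_up(100.0 * v / n, 1)}
            for k, v in sorted(counts.items())
        }

    return {
        "n_members": n,
        "sex_inferred": table(lambda m: m.sex_inferred.value),
        "age_at_diagnosis_band": table(lambda m: m.age_at_diagnosis_band.value),
        "region": table(lambda m: m.region or "missing"),
        "insulin_modality": table(lambda m: m.insulin_modality.value),
        "role_group": table(lambda m: m.role_group.value),
    }


def monthly_density(log: CommunityLog, dyads=None, *, include_admins: bool = True) -> list:
    """Network density of the members-so-far graph at the end of each
    calendar month (None while fewer than 2 members have joined)."""
    if dyads is None:
        dyads = derive_dyads(log)
    out = []
    m = _month_start(log.observation_start)
    end_month = _month_start(log.observation_end)
    window_start = datetime.combine(log.observation_start, time.min)
    while m <= end_month:
        nxt = _next_month(m)
        cutoff = min(nxt, log.observation_end)
        present = {
            mem.member_id
            for mem in log.members
            if (include_admins or not mem.is_admin)
            and mem.join_date < nxt
            and (mem.exit_date is None or mem.exit_date >= m)
        }
        row = {"month": m.isoformat(), "n_members": len(present)}
        if len(present) >= 2:
            g = build_graph(
                [d for d in dyads if d.member_a in present and d.member_b in present],
                (window_start, datetime.combine(nxt, time.min)),
                present,
            )
            row["density"] = density(g)
        else:
            row["density"] = None
        out.append(row)
        m = nxt
    return out


def compile_report(
    *,
    breakdown_: Optional[CommunicationBreakdown] = None,
    ratios_: Optional[EngagementRatios] = None,
    retention_: Optional[dict] = None,
    connectivity_: Optional[dict] = None,
    demographics_: Optional[dict] = None,
    monthly_density_: Optional[list] = None,
    periods_: Optional[list] = None,
    centrality_groups: Optional[dict] = None,
    regression: Optional[dict] = None,
    code_tally: Optional[dict] = None,
) -> dict:
    """Assemble a single report document; stages not run are marked absent
    rather than fabricated."""

    def section(value):
        return value if value is not None else {"status": "absent"}

    return {
        "communication_breakdown": section(
            None
            if breakdown_ is None
            else {
                "counts": breakdown_.counts,
                "total": breakdown_.total,
                "percentages": breakdown_.percentages,
            }
        ),
        "engagement_ratios": section(
            None
            if ratios_ is None
            else {
                "comments_per_authored": ratios_.comments_per_authored,
                "reactions_per_authored": ratios_.reactions_per_authored,
                "views_per_authored": ratios_.views_per_authored,
                "votes_per_poll": ratios_.votes_per_poll,
            }
        ),
        "retention": section(retention_),
        "connectivity": section(connectivity_),
        "demographics": section(demographics_),
        "monthly_density": section(monthly_density_),
        "stable_periods": section(periods_),
        "centrality_groups": section(centrality_groups),
        "leader_effect_regression": section(regression),
        "code_tally": section(code_tally),
    }


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def render_markdown(report: dict) -> str:
    """Human-readable rendering; every number equals the JSON value."""
    lines = ["# Community analysis report", ""]
    bd = report["communication_breakdown"]
    lines.append("## Communication types")
    if "counts" in bd:
        lines.append("")
        lines.append("| kind | count | percent |")
        lines.append("|---|---|---|")
        for k, c in bd["counts"].items():
            lines.append(f"| {k} | {c} | {_fmt(bd['percentages'][k])} |")
        lines.append(f"| total | {bd['total']} | |")
    else:
        lines.append("absent")
    lines.append("")
    er = report["engagement_ratios"]
    lines.append("## Engagement ratios (per authored item)")
    if "comments_per_authored" in er:
        for k in (
            "comments_per_authored",
            "reactions_per_authored",
            "views_per_authored",
            "votes_per_poll",
        ):
            lines.append(f"- {k}: {_fmt(er[k])}")
    else:
        lines.append("absent")
    lines.append("")
    for key, title in (
        ("retention", "Retention"),
        ("connectivity", "Connectivity"),
    ):
        sec = report[key]
        lines.append(f"## {title}")
        if "status" in sec:
            lines.append("absent")
        else:
            for k, v in sec.items():
                lines.append(f"- {k}: {_fmt(v)}")
        lines.append("")
    cg = report["centrality_groups"]
    lines.append("## Relative centrality by group")
    if "status" in cg:
        lines.append("absent")
    else:
        for grp, s in cg.items():
            lines.append(
                f"- {grp}: mean {_fmt(s['mean'])} (SD {_fmt(s['sd'])}, n={s['n']})"
            )
    lines.append("")
    reg = report["leader_effect_regression"]
    lines.append("## Leader effect (OLS)")
    if "status" in reg:
        lines.append("absent")
    else:
        for t in reg["terms"]:
            lo, hi = reg["ci_95"][t]
            lines.append(
                f"- {t}: {reg['coefficients'][t]:.4f} "
                f"(95% CI {lo:.4f} to {hi:.4f}, p={reg['p_values'][t]:.3g})"
            )
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.md").write_text(render_markdown(report), encoding="utf-8")
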