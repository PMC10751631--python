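"""The 80/20 weighted centrality: raw formula, normalization, eligibility,
group contrast, and weight-extreme degree equivalence."""

from datetime import date, datetime

import pytest

from peernet.centrality import (
    CentralityWeights,
    EmptyGroupError,
    group_summary,
    member_mean_relative,
    MemberCentralitySummary,
    period_centrality,
    CentralityScore,
)
from peernet.graph import DyadicInteraction, EngagementTier
from peernet.io_model import Role, RoleInterval, Member
from peernet.segmentation import StablePeriod

from conftest import make_member


def _dyad(a, b, src="x", ts=datetime(2020, 1, 15)):
    return DyadicInteraction(a, b, EngagementTier.HIGH, ts, src)


def test_raw_score_is_weighted_sum_of_events_and_partners():
    # 5 interaction events across 2 distinct partners -> 0.8*5 + 0.2*2
    dyads = [
        _dyad("A", "B", "1"),
        _dyad("A", "B", "2"),
        _dyad("A", "B", "3"),
        _dyad("C", "A", "4"),
        _dyad("C", "A", "5"),
    ]
    scores = {s.member_id: s for s in period_centrality(dyads, {"A", "B", "C"})}
    assert scores["A"].n_interactions == 5
    assert scores["A"].n_partners == 2
    assert scores["A"].raw == pytest.approx(0.8 * 5 + 0.2 * 2)
    assert scores["A"].relative == 1.0


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        CentralityWeights(0.9, 0.2)
    with pytest.raises(ValueError):
        CentralityWeights(-0.2, 1.2)


def test_single_active_member_gets_relative_one():
    scores = {s.member_id: s for s in period_centrality([_dyad("A", "B")], {"A", "B", "C"})}
    assert scores["A"].relative == 1.0 and scores["B"].relative == 1.0
    assert scores["C"].relative == 0.0


def test_interaction_free_period_gives_all_zero_relative():
    scores = period_centrality([], {"A", "B"})
    assert all(s.relative == 0.0 and s.raw == 0.0 for s in scores)


def test_empty_member_set_rejected():
    with pytest.raises(ValueError):
        period_centrality([], set())


def test_duplicated_events_scale_raw_as_expected():
    base = [_dyad("A", "B", "1"), _dyad("A", "C", "2")]
    k = 3
    dup = [
        DyadicInteraction(d.member_a, d.member_b, d.tier, d.timestamp, f"{d.source_event}-{i}")
        for d in base
        for i in range(k)
    ]
    raw0 = {s.member_id: s.raw for s in period_centrality(base, {"A", "B", "C"})}
    rawk = {s.member_id: s.raw for s in period_centrality(dup, {"A", "B", "C"})}
    # raw' = 0.8*k*n_interactions + 0.2*n_partners
    assert rawk["A"] == pytest.approx(0.8 * k * 2 + 0.2 * 2)
    assert raw0["A"] == pytest.approx(0.8 * 2 + 0.2 * 2)


def test_weight_extremes_recover_degree_rankings():
    dyads = [
        _dyad("A", "B", "1"),
        _dyad("A", "B", "2"),
        _dyad("A", "B", "3"),  # A: 3 events 1 partner
        _dyad("C", "D", "4"),
        _dyad("C", "E", "5"),  # C: 2 events 2 partners
    ]
    members = set("ABCDE")
    multi = {m: 0 for m in members}
    simple = {m: set() for m in members}
    for d in dyads:
        multi[d.member_a] += 1
        multi[d.member_b] += 1
        simple[d.member_a].add(d.member_b)
        simple[d.member_b].add(d.member_a)

    s_conn = period_centrality(dyads, members, CentralityWeights(1.0, 0.0))
    rank_conn = sorted(members, key=lambda m: -next(s.raw for s in s_conn if s.member_id == m))
    rank_multi = sorted(members, key=lambda m: -multi[m])
    assert [multi[m] for m in rank_conn] == [multi[m] for m in rank_multi]

    s_part = period_centrality(dyads, members, CentralityWeights(0.0, 1.0))
    rank_part = sorted(members, key=lambda m: -next(s.raw for s in s_part if s.member_id == m))
    rank_simple = sorted(members, key=lambda m: -len(simple[m]))
    assert [len(simple[m]) for m in rank_part] == [len(simple[m]) for m in rank_simple]


def _period(idx, start, end, ids):
    return StablePeriod(idx, date.fromisoformat(start), date.fromisoformat(end), frozenset(ids))


def test_member_mean_and_single_period_flag():
    member = make_member("A", join="2020-01-01")
    periods = [
        _period(0, "2020-01-01", "2020-02-01", {"A"}),
        _period(1, "2020-02-01", "2020-03-01", {"A"}),
    ]
    scores = [
        CentralityScore("A", 0, 2, 1, 1.8, 1.0),
        CentralityScore("A", 1, 1, 1, 1.0, 0.5),
    ]
    (summ,) = member_mean_relative(scores, [member], periods)
    assert summ.mean_relative == pytest.approx(0.75)
    assert not summ.single_period

    (one,) = member_mean_relative(scores[:1], [member], periods[:1])
    assert one.single_period and one.sd_relative == 0.0


def test_leader_scored_only_during_leader_tenure():
    # leader role ends 2020-03-01; periods 3..4 must not count
    jd = date(2020, 1, 1)
    leader = Member(
        member_id="L",
        join_date=jd,
        role_history=(
            RoleInterval(Role.LEADER, jd, date(2020, 3, 1)),
            RoleInterval(Role.REGULAR, date(2020, 3, 1)),
        ),
    )
    periods = [
        _period(i, f"2020-0{i + 1}-01", f"2020-0{i + 2}-01", {"L"}) for i in range(5)
    ]
    scores = [CentralityScore("L", i, 1, 1, 1.0, rel) for i, rel in enumerate([1.0, 0.5, 0.1, 0.1, 0.1])]
    (summ,) = member_mean_relative(scores, [leader], periods)
    assert summ.n_periods == 2
    assert summ.mean_relative == pytest.approx(0.75)


def test_member_with_no_eligible_period_flagged_not_dropped():
    member = make_member("A", join="2020-06-01")
    periods = [_period(0, "2020-01-01", "2020-02-01", {"X"})]
    (summ,) = member_mean_relative([], [member], periods)
    assert summ.no_eligible_periods and summ.n_periods == 0


def _summary(mid, group, mean):
    return MemberCentralitySummary(mid, group, mean, 0.0, 2)


def test_group_summary_means():
    summaries = [
        _summary("L1", Role.LEADER, 0.5),
        _summary("L2", Role.LEADER, 0.6),
        _summary("R1", Role.REGULAR, 0.1),
    ]
    out = group_summary(summaries)
    assert out["leader"]["mean"] == pytest.approx(0.55)
    assert out["regular"]["mean"] == pytest.approx(0.1)
    assert out["leader"]["n"] == 2


def test_group_summary_signals_empty_group():
    with pytest.raises(EmptyGroupError, match="regular"):
        group_summary([_summary("L1", Role.LEADER, 0.5)])


def test_leaders_outscore_regulars_across_seeds(analysis_batch):
    """With 10x leader activity the leader group mean strictly exceeds the
    regular group mean in every simulated community."""
    for res, truth in analysis_batch:
        groups = res["report"]["centrality_groups"]
        assert groups["leader"]["mean"] > groups["regular"]["mean"]
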