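"""End-to-end orchestration: log -> dyads -> periods -> centrality -> effect.

This is the library-level composition the CLI wraps: each step is a pure
function of the log and configuration, so two runs with the same inputs
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import centrality as ctr
from . import graph as gr
from . import inference as inf
from . import segmentation as seg
from . import summary as sm
from .io_model import CommunityLog, Role

__all__ = ["AnalysisConfig", "analyze", "leader_effect"]


@dataclass(frozen=True)
class AnalysisConfig:
    weights: ctr.CentralityWeights = ctr.CentralityWeights()
    tail_rule: str = "P_ge_k_lt_half"
    threshold_k: Optional[int] = None  # fixed threshold overrides the rule
    screening: inf.ScreeningRule = inf.ScreeningRule()
    include_leaders_in_lambda: bool = True


def leader_effect(
    summaries,
    members,
    rule: inf.ScreeningRule = inf.ScreeningRule(),
) -> inf.RegressionResult:
    """OLS of per-member mean relative centrality on leader status, with
    name-inferred sex and age band screened as covariates."""
    by_id = {m.member_id: m for m in members}
    rows = [s for s in summaries if not s.no_eligible_periods and s.role_group is not Role.ADMIN]
    if len(rows) < 3:
        raise ValueError("too few scored members for regression")
    y = np.array([s.mean_relative for s in rows])
    leader = np.array([1.0 if s.role_group is Role.LEADER else 0.0 for s in rows])
    sex = [by_id[s.member_id].sex_inferred.value for s in rows]
    age = [by_id[s.member_id].age_at_diagnosis_band.value for s in rows]

    candidates: dict = {}
    columns: dict = {}
    for name, values in (("sex_inferred", sex), ("age_band", age)):
        mat, names, _ = inf.encode_categorical(values)
        if mat.shape[1] > 0:
            candidates[name] = mat
            columns[name] = [f"{name}{n}" for n in names]
    return inf.screen_and_fit(y, ("leader", leader), candidates, rule, columns)


def analyze(log: CommunityLog, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run every stage on a validated log and compile the report dict."""
    dyads = gr.derive_dyads(log)
    bd = sm.breakdown(log)
    growth = seg.monthly_growth(log, include_leaders=config.include_leaders_in_lambda)
    if config.threshold_k is not None:
        k = config.threshold_k
    else:
        lam = seg.mean_arrival_rate(growth)
        k = seg.growth_threshold(lam, config.tail_rule) if lam > 0 else 1
    periods = seg.stable_periods(growth, k, log)
    scores, summaries = ctr.centrality_pipeline(log, dyads, periods, config.weights)
    try:
        groups = ctr.group_summary(summaries)
    except ctr.EmptyGroupError:
        groups = None
    try:
        regression = leader_effect(summaries, log.members, config.screening).to_dict()
    except ValueError:
        regression = None

    report = sm.compile_report(
        breakdown_=bd,
        ratios_=sm.ratios(bd),
        retention_=sm.retention(log),
        connectivity_=sm.connectivity(log, dyads),
        demographics_=sm.demographics(log),
        monthly_density_=sm.monthly_density(log, dyads),
        periods_=seg.periods_to_rows(periods, growth),
        centrality_groups=groups,
        regression=regression,
    )
    return {
        "report": report,
        "dyads": dyads,
        "growth": growth,
        "threshold_k": k,
        "periods": periods,
        "scores": scores,
        "summaries": summaries,
    }
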