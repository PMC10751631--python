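# Methods

This note records the models, conventions, and deliberate design choices
behind `peernet`, in the order the pipeline applies them.

## Data model and validation

A community log is a roster of members (role history, join/exit dates,
optional demographics) plus a flat event stream.  Six event kinds exist:
post, comment, reaction, poll, vote, view.  Parent references are
constrained by kind — comment→post, reaction→post or comment, vote→poll,
view→post or poll; posts and polls are roots.  A view's parent is
*optional*: platform exports often report views only in aggregate, and no
network statistic consumes view targets, so the schema recommends but does
not require attribution.  Validation is total: a file either parses into a
log satisfying every invariant (unique ids, resolvable actors and parents,
child timestamps ≥ parent, events inside the observation window,
non-overlapping role intervals) or fails with a located error.  Timestamps
are ISO-8601 and treated as UTC; calendar months are derived by truncation.

Role intervals are half-open `[start, end)`: a leader who stepped down on
the first of a month is not a leader during that month.  Membership, by
contrast, is inclusive of the exit date.

## Engagement tiers and the interaction graph

Posts and comments are high engagement, reactions medium, views low.  The
two kinds outside that canon are polls and votes: polls are authored
content and are classed high with posts, votes are reaction-like and
classed medium.  Both assignments are configurable (`classify_tier`'s
`tiers` argument) because the choice is a modelling convention, not a fact
of the data.

Every non-view child event yields one dyadic interaction between the
child's actor and the *parent* event's author — a reaction to a comment
links reactor↔commenter, not reactor↔thread-root, since the parent is the
content actually being engaged with.  Self-replies yield nothing.  The
interval graph over a half-open window `[start, end)` keeps the full
multi-edge count per unordered pair; density and cliques use the simple
edge set (≥ 1 interaction).  Density is `|edges| / (n(n−1)/2)` and is
undefined (raised, not NaN) below two nodes.  Maximal cliques come from
pivoting Bron–Kerbosch enumeration with a deterministic post-hoc ordering
(size descending, then lexicographic); the test suite pins it to a
brute-force subset oracle on all random graphs up to 12 nodes.

## Stable membership periods

Let λ be the mean monthly count of new members over the window (by default
all non-admin joins, leaders included; both excludable).  The growth
threshold is derived from Poisson(λ) by direct pmf summation under one of
two readings of "the lowest count with < 50% probability of occurrence":

- `P_ge_k_lt_half` (default): smallest k with P(X ≥ k) < ½;
- `P_gt_k_lt_half`: smallest k with P(X > k) < ½ (the Poisson median).

At λ ≈ 6.42 (≈ 212 regular members over 33 months) the rules give 7 and 6
respectively; the strict-tail rule reproduces the threshold of 6 used in
the community this package was built around, and `k` can also be fixed
directly.  The observation window is then cut at the start of every
calendar month whose arrivals reach `k`; the first period always begins at
the observation start, so periods tile the window exactly (a property
test over random growth sequences).

## Relative centrality

For member *i* in period *t*:

    raw_it = w_c · n_interactions_it + w_p · n_partners_it,   w_c = 0.8, w_p = 0.2

`n_interactions` counts high/medium dyadic interaction events involving
the member inside the period (each event counts once for each endpoint);
`n_partners` counts distinct other members so connected.  Reading the
first term as event counts rather than unique connections is what makes
the 80/20 mixture non-degenerate — with both terms as unique partners the
weights would cancel.  Relative centrality is `raw / max_j raw_jt`; ties
at the maximum all score 1.0, and a period with no interactions scores 0
for everyone (avoiding 0/0).  With weights (1, 0) the induced ranking is
multi-edge degree; with (0, 1) simple degree — both checked against
independent degree computations.

Per-member means are taken over eligible periods: leader-role overlap for
leaders, membership overlap for regular members (members joining
mid-period are scored over the whole period; no exposure adjustment, since
the period design already controls membership drift).  SDs are sample SDs;
a single eligible period yields SD 0 with a flag, and a member with no
eligible period is flagged rather than dropped.  Admin accounts are kept
in the data model (they may appear in graphs) but are excluded from
per-period score sets, group contrasts, and all descriptive denominators;
interactions with admins consequently do not count toward member scores.

## Leader-effect regression

OLS is implemented in the package (least squares via `numpy.linalg.lstsq`,
covariance `σ²(XᵀX)⁻¹`, 95% CIs and two-sided p-values from the t
distribution on n − p df); statsmodels serves only as an independent
cross-check in the tests.  Rank deficiency raises with the collinear terms
named.  Zero residual variance (constant outcome, exact fit) is flagged;
p-values then default to 1 for zero coefficients.

Covariate screening: each candidate (a column, or an indicator block for a
categorical) is tested univariately against the outcome; p ≤ 0.25 enters
the multivariable model; a single backward pass drops candidates with
multivariable p > 0.05; the final model is refit.  Blocks are tested with
partial F-tests (identical to the t-test for single columns).  The leader
indicator is always retained.  Categoricals use reference-level indicator
coding with the most frequent level as reference, and "missing" is an
explicit level — members with unspecified fields stay in the model.  The
unit of analysis is the member-level mean relative centrality.

Monte-Carlo calibration (true effect 0.5, noise SD 0.05, n = 222, 200
replicates) verifies mean-estimate bias < 0.02 and CI coverage within
[0.90, 0.99].

## Support-code tallies

The taxonomy is shipped in code and exportable as `codebook.json`:
direction (seeking / providing / neither), five support categories, 27
third-level support codes, and 12 disjoint non-support codes.  Tallies
count applications, not communications (a 3-code post contributes 3);
direction is carried per assignment and applied to its support-code
applications.  Conservation — categories sum to the support count,
third-level codes to their category — is asserted on every tally.
Proportions use decimal half-up rounding at 1 decimal by default, 2 where
finer precision is conventional; zero denominators report `None`.

## Descriptive surface

Communication-type percentages are half-up at 2 decimals.  Engagement
ratios use posts + polls as the authored-item denominator (the only choice
consistent simultaneously with comment, reaction, view, and vote ratios on
the margins fixture): comments and reactions per authored item at 1
decimal, views per authored item and votes per poll to the nearest
integer.  Retention and connectivity percentages (1 decimal) use all
non-admin members as denominator; "connected" means appearing in ≥ 1
high/medium dyad over the full window.  The compiled report is a pure
function of log + configuration; the markdown rendering contains exactly
the JSON's numbers.

## Synthetic communities

`simulate_community` emulates the observed shape of a moderated
peer-support community.  Defaults (chosen once, from the aggregate shape
the analysis assumes): 33 months; 10 leaders present from month 1; regular
members arriving Poisson(6.4)/month; per-member monthly post rate 0.15
with a 10× leader multiplier; polls Poisson(0.45)/month authored by
leaders; per (member, content) independent Bernoulli engagement —
comment 0.02 (leaders 10×), reaction 0.04 (leaders 3×; reactions are
secondary to the trained behaviours of posting and commenting), view 0.5;
poll votes targeting ≈ 27 per poll; exit hazard 0.004/member/month, never
in the join month.  These yield ≈ 85% views, ≈ 33 authored items and ≈ 57
views per item monthly, and a full-window exit probability of ≈ 12% per
member (the aggregate exit share is lower because later joiners have less
exposure).  Randomness derives from one seed via per-month spawned
substreams, so a log is byte-reproducible from (config, seed).

What the simulator does *not* model: preferential attachment or
reciprocity (engagement draws are independent), content text, seasonal or
campaign effects, and lurker-to-poster transitions.  Passing recovery
tests therefore show that the pipeline detects a planted activity
asymmetry of the configured size under Poisson/Bernoulli noise — not that
real communities satisfy those independence assumptions.

`fixture_from_margins` builds a deterministic log hitting requested
event-kind counts, member count, connected-member count, and exit count
exactly, via a hub-and-spokes construction (one hub authors all roots;
each further connected member contributes one child event; leftovers are
recycled among connected members; views round-robin over the roster and
create no ties).  It fixes the *margins*, not the network topology — it is
the right instrument for descriptive statistics, and deliberately wrong
for centrality or clique structure.  `code_assignments_from_margins`
likewise pins category/direction totals, assigning each category's count
to its first third-level code (the margins do not constrain the split) —
a synthetic stand-in for a human-coded table.

## Problem sizes

Tests run the simulator at default scale (~80k events) across 20 seeds for
calibration and recovery, brute-force clique oracles to 12 nodes, and the
Monte-Carlo OLS calibration at 200 replicates; the acceptance script uses
the same sizes.  These sizes were chosen to make the sampling checks
well-powered while keeping the whole suite fast on a single CPU.

## Known limitations

- The dyad rule attributes engagement to the parent's author only; broadcast
  effects (a comment read by the whole thread) are not modelled as ties.
- Exposure time within a period is ignored (a member joining on the last
  day of a period is normalised against members present throughout).
- The screening procedure is the classical two-stage alpha filter; it
  inherits that procedure's known instability under collinear candidates.
- View counts are accepted unattributed, so view-weighted extensions would
  need attributable exports.
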