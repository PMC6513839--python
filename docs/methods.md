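# Methods

## Data model

An *agonistic event* is one timed winner/loser interaction labelled with
one of five ethogram behaviors: fighting, chasing, mounting, subordinate
posture, induced flee.  The winner ("actor") is the animal that chased,
bit, mounted, or forced the other to display subordinate behavior; for the
last two behaviors the displaying/fleeing animal is therefore the
*recipient*.  Days are 1-based; times are seconds within that day's
observation session, not wall clock.  The default observation schedule is
2 h per day for 14 days, configurable per day.

When behaviors between the same two animals co-occur within 2 s they are
collapsed to a single event with priority fighting > chasing > mounting >
subordinate posture > induced flee.  Clusters are anchored at the earliest
event of a run: every same-dyad event within the window of the cluster's
first member joins it, and the surviving (highest-priority) event is
stamped with the cluster's onset time.  The onset-time stamp is what makes
the rule idempotent and order-independent: consecutive survivors are
guaranteed to be more than one window apart.  Chains of co-occurrence
longer than one window therefore resolve to one event per window-anchored
cluster, a deterministic choice among the several defensible readings of
"co-occurring".

All statistics operate on the frequency sociomatrix **W** with entries
s_ij = wins of i over j, dyad totals n_ij = s_ij + s_ji.  A dyad is
*decided* when s_ij ≠ s_ji, *tied* when s_ij = s_ji > 0, *unknown* when
n_ij = 0.  Unknown dyads are plain zero counts; no sentinel values.

## Hierarchy statistics

**David's scores.**  P_ij = s_ij/n_ij (0 for unknown dyads);
w = Σ_j P_ij, w2 = Σ_j P_ij w_j, l = Σ_j P_ji, l2 = Σ_j P_ji l_j;
DS = w + w2 − l − l2; NormDS = (DS + N(N−1)/2)/N ∈ [0, N−1].  By default
raw proportions are used, because DS is a win-proportion measure; the
dyadic correction D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1), which discounts
sparsely observed dyads, is available behind a flag since both variants
circulate in the literature.  ΣDS = 0 is asserted to 1e−9 absolute.

**Steepness** is the absolute OLS slope of descending NormDS against rank
position 1..N — 1 for a maximally uneven hierarchy, 0 for a flat one.  It
is exactly 1 on any perfectly linear, fully decided matrix.

**Landau's h and modified h′.**  For a complete tournament,
h = 12/(N³−N) Σ_a (V_a − (N−1)/2)² with V_a the number of individuals a
dominates.  h′ handles tied/unknown dyads by directing each at random with
probability ½ per side and averaging h over 1000 such resolutions
(configurable, seeded).  The mean-over-resolutions formulation was chosen
over the closed-form tie correction because it is simple, seedable, and
converges to the same value; with no undecided dyads it equals h exactly
and ignores the seed.  For N = 3 all-unknown data the expectation is
exactly 0.75 (6 of the 8 equally likely tournaments are transitive), which
the test suite uses as an analytic anchor.

**Triangle transitivity.**  Among triads whose three dyads are all
strictly decided, P_t is the transitive proportion and
ttri = 4(P_t − 0.75), so 0 is the random-tournament expectation and 1
means no cycles.  Triads containing a tie or unknown dyad are excluded; if
no complete triad exists the statistic is undefined (NaN) rather than an
error, so day-by-day emergence tables can carry early sparse days.

**Directional consistency** DC = Σ|s_ij − s_ji| / Σ n_ij over dyads.
Tied dyads contribute their events to the denominator and 0 to the
numerator.  **Despotism** is the top-ranked individual's share of all wins,
with "top-ranked" taken from the David's-score order by default (ties
broken by total wins, then label) since that order is intrinsic to the
matrix.  **Gini** uses the pairwise-difference form
G = Σ_ij |x_i − x_j| / (2n² x̄), computed via the sorted-rank identity;
its maximum for length n is (n−1)/n.

**I&SI ranking** minimizes lexicographically (I, SI): I = number of dyads
in which the lower-ranked animal dominates the higher-ranked one, SI = sum
of their rank distances.  The search is pairwise-swap hill climbing —
steepest descent over all C(N,2) swaps — started from the David's-score
order, with shuffled restarts (default 100, seeded).  On matrices up to
N = 5 the heuristic provably matches exhaustive search in the test suite;
for N = 12 the optimum is not guaranteed, as with all I&SI
implementations.

## Randomization inference

p = (1 + #{randomized ≥ observed}) / (M + 1), one-sided as the statistics
are all "larger = more structured", with the add-one correction so p is
never 0; the attainable minimum is 1/(M+1).  Two null schemes:

- **dyad_bernoulli** — each dyad's n_ij outcomes redrawn as
  Binomial(n_ij, ½); preserves every dyad total.  Default for DC and
  steepness, whose signal is within-dyad asymmetry.  The steepness null is
  not pinned down by convention; this choice is documented and
  configurable.
- **tournament_uniform** — each interacting dyad's direction a fair coin,
  binary outcome; preserves N and the decidedness pattern.  Default for h′
  and ttri, which are order statistics.

QAP correlates the off-diagonal cells of two sociomatrices (Pearson r) and
builds the null by permuting vertex labels — rows and columns jointly — of
the second matrix, preserving its dyadic structure; both one-sided tails
are reported since directionality conventions differ between studies.

## Glicko ratings

Every behavioral interaction is one rating period (ratings are recalculated
after every event).  Per period: all deviations inflate to
min(√(RD² + c²), 350) with c = 3; the winner and loser then update by the
standard Glicko equations (q = ln10/400, g(RD) = 1/√(1 + 3q²RD²/π²),
E = 1/(1 + 10^(−g(RD_opp)(r − r_opp)/400))); bystanders keep the inflated
deviation and unchanged rating.  Everyone starts at (2200, 300).  The
initial deviation 300 and cap 350 are the system's common defaults; all
four constants are config fields.  The per-event (rather than per-batch)
reading of the inflation constant is implemented deliberately: it matches
the "recalculated after every interaction" protocol, and under it an idle
animal's uncertainty grows slowly while its rating is untouched.  Rank
trajectories break rating ties by cumulative wins, then label, so
trajectories are deterministic.

The most dominant / most subordinate k animals (default 2) are selected by
final Glicko rating and cross-checked against the NormDS order; the
selection reports whether the two systems agree and exposes both orders
when they do not.

## Synthetic colony generator

The generator emulates the study conditions the pipeline targets: cohorts
of 12 females observed 2 h/day for 14 days, with roughly 400 agonistic
events per cohort.  Structure:

- A latent linear order is drawn uniformly.  Encounters arrive per day and
  behavior as Poisson counts with rate base_event_rate × mix_b × hours,
  where base_event_rate defaults to 15 events/observed hour and the mix is
  fighting 0.40 / chasing 0.45 / mounting 0.15 (fighting and chasing occur
  at clearly higher rates than mounting).  Fighting decays by 0.9×/day
  (hierarchies are established early and overt fighting declines; chasing
  and mounting stay flat).
- For each encounter the initiator is drawn with weight
  exp(−α(rank − 1)), α = 0.3 by default (aggression concentrated toward
  the top, but far from despotic), the partner uniformly; the
  higher-ranked member wins with probability p_c = 0.9 (the rank-threshold
  Bernoulli keeps DC analytically predictable: E[DC] → 2p_c − 1; a
  rank-distance logistic winner model is available but not default).  The
  recorded actor is the winner.  A consequence worth noting: with uniform
  initiation (α = 0) the alpha's win share is 2p_c/N, not 1/N — despotism
  reflects both participation and win probability.
- Only a propensity subset (default half) of individuals ever mounts;
  mounting events whose winner lacks propensity are recorded as chasing.
  This reproduces the strongly unequal distribution of mounting without
  attempting to match any particular Gini value.
- Estrus follows the cyclic chain proestrus → estrus → metestrus →
  diestrus with geometric dwell (stay probability 1 − 1/mean); dwell means
  default to 1.3/2.0/1.3/1.0 days, and each individual's estrus dwell is
  scaled by 1 + g·(N − rank)/(N − 1) with gradient g = 0.5, so dominants
  spend the most time in estrus — a deliberately simplified stand-in for
  the extended, rank-dependent cycles of group-housed females.  5% of
  smears are recorded as undetermined without perturbing the chain.

What the generator does *not* emulate: individual day-to-day rate
variation beyond Poisson noise, estrus effects on behavior rates,
coalitions or audience effects, rank dynamics (the latent order is fixed
from day 1), and any physiological layer.  Passing parameter-recovery
tests therefore shows the pipeline detects the effects it targets at
realistic sizes and sample sizes — not that real colonies satisfy the
generator's assumptions.

## Numerical and scale choices

Randomization defaults are M = 1000 draws (the CLI's `--perms`), h′ uses
1000 tie resolutions, and h′ evaluated inside null draws uses 100
resolutions — the null distribution of a mean is far less resolution-
sensitive than the point estimate.  The test suite exercises the same code
paths at reduced sizes (M of 50–300, 8–25 simulation replicates, cohorts
of 6–12) chosen so the full suite completes in well under a minute while
keeping Monte-Carlo error small relative to every asserted margin.
Degenerate inputs are contracts, not crashes: empty matrices raise for
DC/despotism/Gini, h′ requires N ≥ 3, ttri returns NaN without complete
triads, and all-undetermined estrus individuals get NaN proportions.

## Known limitations

- I&SI is a heuristic beyond N ≈ 8; ties in (I, SI) between distinct
  orders are resolved by search history, not by a canonical rule.
- The h′ randomization null treats tied dyads as undirected; protocols
  that drop tied dyads instead will give slightly different p-values on
  tie-heavy data.
- Hourly-rate tables assume the schedule covers every event day; partial
  sessions must be expressed through per-day hours.
- The estrus chain has no refractory structure; it cannot produce the
  40-day disrupted cycles reported in very large groups.
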