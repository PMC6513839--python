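# domhier

Dominance-hierarchy analysis for group-housed rodents.

When animals living in a group compete over resources, repeated wins and
losses in agonistic encounters (fights, chases, mounts, forced subordinate
displays) organize the group into a dominance hierarchy.  `domhier` takes
timed winner/loser event logs — the kind produced by all-occurrence live
scoring of mouse colonies — and answers the standard questions about
hierarchy structure: Is the hierarchy linear?  How unequally is power
distributed?  How quickly did the order emerge, and who ended up on top?
It is aimed at behavioral researchers analysing rodent (or any dyadic
winner/loser) social data, and ships a synthetic colony generator so the
whole pipeline runs and can be validated with no data collection at all.

## What it computes

For an N×N winner-by-loser frequency sociomatrix with entries
*s<sub>ij</sub>* (wins of *i* over *j*, dyad totals
*n<sub>ij</sub> = s<sub>ij</sub> + s<sub>ji</sub>*):

- **Landau's modified h′** — linearity of the implied order,
  *h = 12/(N³−N) · Σ<sub>a</sub> (V<sub>a</sub> − (N−1)/2)²* where
  *V<sub>a</sub>* is the number of individuals *a* dominates; tied/unknown
  dyads are resolved at random and *h* averaged over resolutions.
- **Triangle transitivity** — *t<sub>tri</sub> = 4(P<sub>t</sub> − 0.75)*
  with *P<sub>t</sub>* the proportion of fully decided triads that are
  transitive (0 = random expectation, 1 = all transitive).
- **David's scores** — *DS = w + w₂ − l − l₂* from dyadic win proportions
  *P<sub>ij</sub> = s<sub>ij</sub>/n<sub>ij</sub>*, normalized to
  *NormDS ∈ [0, N−1]*; **steepness** is the absolute OLS slope of ordered
  NormDS against rank.
- **Directional consistency** —
  *DC = Σ(max(s<sub>ij</sub>,s<sub>ji</sub>) − min(s<sub>ij</sub>,s<sub>ji</sub>)) / Σ n<sub>ij</sub>*.
- **Despotism** — the alpha's share of all wins; **Gini coefficients** of
  win and loss counts; **I&SI rank order** (minimizing the number, then the
  strength, of rank inconsistencies).
- **Randomization p-values** for all of the above (one-sided, add-one
  corrected) and **QAP correlations** between behavior-specific matrices.
- **Glicko rating trajectories**: every individual starts at rating 2200
  and ratings update after every single interaction (inflation constant
  c = 3 per event), tracing how individual ranks emerge over time.
- **Hierarchy emergence by day** (cumulative h′/ttri with significance),
  hourly behavior rates by rank/day/behavior, and descriptive estrus-state
  summaries (state proportions, rank crosstabs, rates by state).

## Worked example

```python
from domhier import (SyntheticConfig, simulate_colony,
                     build_win_loss_matrix, full_report, rank_isi)

cfg = SyntheticConfig(cohort="A", seed=42)   # 12 females, 14 days, 2 h/day
events, truth = simulate_colony(cfg)
W = build_win_loss_matrix(events)
report = full_report(W, n_randomizations=1000, seed=42)
for k, v in report.to_dict().items():
    print(f"{k:12s} {v:.3f}" if isinstance(v, float) else f"{k:12s} {v}")
print("I&SI order:", rank_isi(W, seed=42))
```

prints

```
h_prime      0.878
p_h_prime    0.001
ttri         0.900
p_ttri       0.001
steepness    0.650
p_steepness  0.001
dc           0.801
p_dc         0.001
despotism    0.296
gini_wins    0.533
gini_losses  0.160
n_events     341
n_individuals 12
I&SI order: ['A01', 'A08', 'A07', 'A10', 'A12', 'A04', 'A03', 'A06', 'A05', 'A11', 'A02', 'A09']
```

Read: this simulated cohort of 12 females produced 341 agonistic events;
the hierarchy is significantly linear (h′ = 0.88, ttri = 0.90, both
p = 1/1001, the smallest p attainable with 1000 randomizations) and
directionally consistent (80% of interactions flow down the hierarchy), yet
not despotic — the alpha performed only 30% of all wins.  The I&SI order
recovers the latent order used by the generator up to one adjacent swap of
mid-ranked animals.

The same pipeline runs from the shell:

```
domhier simulate --seed 7 --cohorts 8 --out data/
domhier analyze --events data/events.csv --estrus data/estrus.csv \
    --seed 7 --perms 1000 --out results/
domhier compare results_females/metrics.csv results_males/metrics.csv
```

`analyze` writes per-cohort metric tables, per-behavior DC/Gini tables,
pairwise QAP correlations (fighting/chasing/mounting), Glicko trajectories,
day-by-day emergence tables, hourly-rate and estrus summaries, plus a
manifest recording every seed so reruns are byte-identical.

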