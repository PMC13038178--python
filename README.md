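# mhengage

Engagement analytics and pre/post outcome analysis for mobile-health
(mHealth) app usage logs, built around the analysis design of a 4-week
single-arm mobile-nutrition feasibility study in cancer survivors.

Digital health interventions record every user interaction as a
timestamped log entry, but feasibility questions — did participants keep
using the app, how often, how regularly, and did heavier use track better
outcomes? — require turning those raw taps into *sessions*, engagement
metrics and stratified pre/post comparisons. `mhengage` implements that
pipeline end to end for analysts of small mHealth trials:

- **Sessionization with data-driven threshold selection.** A session is a
  maximal run of events whose consecutive gaps are all below a threshold
  τ (gap ≥ τ starts a new session). The operating τ is chosen by sweeping
  a grid (0–60 min in 10-min steps by default), counting total sessions
  N(τ), and taking the elbow of the curve — the interior grid point
  maximizing the discrete second difference N(τ−s) − 2N(τ) + N(τ+s), with
  a fallback (default 10 min) when the curve has no knee.
- **Engagement profiling.** Cumulative usage minutes (session durations
  floored at 0.5 min so single-tap sessions count), sessions/day, longest
  streak of consecutive active days with ≥14/21/28-day flags, inter-session
  gap mean/SD, adherence (fraction of window days with ≥1 session), and a
  regular/irregular daily-pattern label (daily use with within-day gaps
  ≤ 7 h).
- **Patient-reported-outcome scoring.** EORTC QLQ-C30 v3.0 (15 scales,
  linear 0–100 transform, half rule for missing items) and the NQ-2021
  nutrition quotient (Balance / Moderation / Practice domains plus a
  weighted total; the official Korean Nutrition Society weights are not
  public, so a clearly-labelled equal-weight configuration ships as the
  default).
- **Nonparametric analysis.** Two-sided Wilcoxon signed-rank pre/post
  tests (exact null distribution at small n, normal approximation with tie
  and continuity corrections otherwise), engagement–outcome Spearman or
  Pearson correlations, engagement-stratified and demographic subgroup
  comparisons (flagged exploratory, no multiplicity adjustment), and the
  single-proportion sample-size formula n₀ = z²p(1−p)/e² with
  finite-population correction n₀/(1 + (n₀−1)/N).
- **Synthetic cohorts.** No individual-level data are published for this
  kind of study, so a seedable generator produces cohorts with the assumed
  structure — lognormal between-participant session propensity, Poisson
  daily session counts anchored at meal times, bursty within-session event
  streams, geometric dropout, and a configurable linear coupling between
  standardized engagement and outcome change — with ground truth recorded
  for every latent quantity.

## Worked example

Run the whole pipeline on a simulated 27-participant, 28-day cohort:

```bash
mhengage run-all --config config.yaml          # or: python -m mhengage.cli
mhengage report demo_run
```

with `config.yaml`:

```yaml
simulate: {n_participants: 27}
outdir: demo_run
seed: 1
```

which prints:

```
mhengage run summary
====================
participants enrolled:      27
completed post-assessment:  27
retention:                  27/27 = 100.0%
chosen session gap:         10 min
mean sessions/day:          2.21
median cumulative use:      176.1 min
median adherence:           89.3%

strata sizes:
  time_median: high_time=14, low_time=13
  frequency: high_frequency=5, low_frequency=22
  regularity: irregular=27
  streak_14: streak_ge_14=12, streak_lt_14=15
  streak_21: streak_ge_21=7, streak_lt_21=20
  streak_28: streak_ge_28=1, streak_lt_28=26
```

Reading this: all 27 simulated enrollees completed (no early dropouts at
this seed); the elbow procedure picked a 10-minute session gap; the cohort
averaged 2.21 sessions/day with a median of 176 cumulative minutes over
the 4 weeks and used the app on 89% of days. The run directory also holds
`sessions.csv`, `session_count_curve.csv`, `profiles.csv`, `scores.csv`,
`paired_tests.csv` (Wilcoxon rows per scale, overall and per stratum),
`correlations.csv` and a `manifest.json` echoing config, seed and row
counts. The same library calls are available directly:

```python
from mhengage import SimConfig, generate_cohort, sessionize_all, threshold_sweep, select_elbow

cohort = generate_cohort(SimConfig(n_participants=27, seed=1))
tau = select_elbow(threshold_sweep(cohort.events)).threshold_min   # -> 10.0
sessions = sessionize_all(cohort.events, tau)
```

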