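# Methods

This note documents the models, rules and numerical choices behind
`mhengage`, and what the synthetic cohorts do and do not establish about
real app-log data.

## Sessionization

Events are UTC instants at second resolution; duplicates (simultaneous
taps) are retained. Two consecutive events of one participant share a
session **iff** their gap is strictly less than the threshold τ; a gap
≥ τ starts a new session. Consequences of the strict convention: τ = 0
degenerates to one session per event, and duplicate timestamps always
share a session for any τ > 0. Events are first restricted to each
participant's intervention window, the half-open interval
`[enrollment, enrollment + 28 days)`.

The operating τ is data-driven. Total session count N(τ) is computed over
a grid (default 0–60 min in 10-min steps, the 0 point included even
though it degenerates to the event count); N(τ) is nonincreasing because
larger thresholds only merge sessions. The *elbow* is verbal in most
descriptions of this procedure; we operationalize it as the interior grid
point maximizing the discrete second difference
`N(τ−s) − 2N(τ) + N(τ+s)` — the point where the steep initial drop ends —
with ties broken toward the smallest τ. When the maximum second
difference is ≤ 0 (linear or constant curves have no knee) the selector
returns a configurable fallback (default 10 min, a typical operating
value for meal-logging apps) and flags it. A `fixed` mode bypasses the
sweep, supporting the older 30-minute convention for session boundaries.

## Engagement metrics

Per participant, from sessions within the window:

| metric | definition | default |
|---|---|---|
| `total_usage_min` | Σ max(end − start, floor) | floor 0.5 min |
| `sessions_per_day` | n_sessions / window_days | window 28 d |
| `max_streak_days` | longest run of consecutive active calendar days | tz UTC |
| `adherence` | distinct active days / window_days | — |
| `mean_gap_min`, `sd_gap_min` | over gaps between consecutive sessions (end → next start); SD uses ddof = 1 | NaN below 2 (3) sessions |

A session's raw span is end − start, which is 0 for single-event
sessions; the floor keeps cumulative time from being dominated by
zero-length sessions while leaving multi-minute sessions untouched.
Calendar days are evaluated in a configurable timezone (default UTC) and
a session belongs to the day containing its start; day-boundary choices
matter only for sessions spanning midnight, which the generator makes
rare.

**Regularity.** "Regular" use means daily use spread through the day. The
implemented rule: regular iff (a) the fraction of window days with ≥ 1
session meets a coverage threshold (default 1.0, i.e. daily use), (b)
every active day has at least 2 sessions, so within-day intervals exist
at all (the morning/afternoon/evening pattern), and (c) every within-day
gap between consecutive sessions is ≤ 7 h. Overnight gaps are exempt —
under daily coverage the next day is always active. A
single-session-per-day pattern is therefore *irregular* even with perfect
coverage: its inter-use intervals are ~24 h, not ≤ 7 h. This is an
interpretation (the threshold-based wording in the field leaves the
overnight case open) and every piece of it is configurable
(`RegularityRule`).

**Stratification.** Four schemes mirror common engagement splits:
total-time at the cohort median (inclusive ≥, even n takes the midpoint
of the central pair, so ties at the median land in the high group);
sessions/day at an inclusive 2.5/day cutoff; streak ≥ k for
k ∈ {14, 21, 28} (nested by construction); and the stored regularity
label.

## Questionnaire scoring

**EORTC QLQ-C30 v3.0.** The scale→item map and formulas follow the
published scoring manual and are shipped as a JSON instrument spec rather
than hard-coded. Raw score RS = mean of answered items, scored only when
at least half the items are answered (half rule). Functional scales:
`(1 − (RS−1)/range)·100`; symptom scales and global health:
`((RS−1)/range)·100`; range is 3 for the 4-point items (1–28) and 6 for
the 7-point global items (29–30). Scores are reported with `n_answered`
so downstream analyses can audit missingness.

**NQ-2021.** Each item response is normalized to u ∈ [0, 1] by its
response range and keying direction (Moderation items are reverse-keyed:
low frequency of unhealthy behaviour is best); a domain scores
`100·Σwᵢuᵢ/Σwᵢ` over answered items under the same half rule, and the
total is the domain-weighted mean. The official item map and weights of
the Korean Nutrition Society algorithm are not public; the bundled
18-item / 3-domain structure (8 Balance, 6 Moderation, 4 Practice, all
on 1–5 scales) and the equal-weight configuration are labelled synthetic
stand-ins, so absolute NQ scores from this package are internally
consistent but not comparable to published NQ norms. "Implementation" is
accepted as an alias of "Practice". With equal weights the domain score
reduces to 100 × the mean normalized item, which the tests exploit.

## Statistical analysis

Pre/post comparisons use the two-sided Wilcoxon signed-rank test on
post − pre differences, complete cases per scale. Zero differences are
discarded by default (classical Wilcoxon; Pratt selectable). `auto` mode
uses the exact null distribution when ≤ 25 nonzero differences carry no
tied absolute values, else the normal approximation with tie and
continuity corrections; p-values come from `scipy.stats.wilcoxon`, while
the reported statistic is always W⁺ (rank sum of positive differences)
computed in-package. All-zero differences yield a degenerate flag with
p = 1. The exact path is verified in the tests against an independent
full 2ⁿ sign-assignment enumeration.

Engagement–outcome association defaults to Spearman (robust for n ≈ 24
bounded scores; Pearson selectable — published reports of such
correlations rarely state the estimator). Stratified and subgroup results
carry an `exploratory: true` flag and no multiplicity adjustment,
matching the descriptive framing such feasibility analyses use.

Sample size for a single proportion: `n₀ = z²p(1−p)/e²` with the
two-sided normal quantile, finite-population correction
`n₀/(1+(n₀−1)/N)`, rounded up. With 90% confidence, e = 0.10, p = 0.5 and
N = 2153 this gives 66.

## The synthetic cohort generator

The generator emulates the study conditions rather than any participant's
data. Defaults (all `SimConfig` fields):

- n = 27 enrolled, 28-day window, enrollment staggered over 60 days from
  2024-10-01;
- daily session propensity lognormal across participants with mean 2.3
  sessions/day and SD 0.9; daily session counts Poisson(propensity);
- session start times Gaussian around meal anchors 08:00/12:30/19:00
  (SD 0.75 h); consecutive sessions forced ≥ the declared 10-min gap
  apart;
- events per session 1 + Poisson(52) (≈ 53, the events-per-session ratio
  typical of meal-photo logging); intra-session gaps truncated-exponential
  with mean 0.057 min, capped 2 s below the declared gap so that
  second-rounding cannot blur a session boundary — these two choices make
  the implied median cumulative usage ≈ 175 min over the window;
- dropout: geometric with hazard 0.004/day (≈ 1 in 9 over 4 weeks);
  dropouts before day 15 contribute no post questionnaires;
- outcomes: pre targets drawn per scale around baseline means/SDs typical
  of disease-free survivors (e.g. Moderation 76.6 ± 15.4, appetite loss
  17.9 ± 22.0); post target = pre + β·z + N(0, σ) clipped to [0, 100],
  with z the cohort-standardized true cumulative usage, β per-scale
  coupling (default +4.4 Moderation, −4.0 appetite loss, 0 elsewhere) and
  σ = 8 points; targets are then realized as integer item responses, so
  observed scores are quantized.

Item-response generation inverts the scoring formulas: a target score
becomes an integer "offset budget" spread as evenly as possible over a
scale's items, guaranteeing re-scored output within half a quantization
step (`100/(n_items·range)` points) of the target. For coupling-recovery
checks, β = 4.84 with σ = 8 puts the latent Pearson correlation at
β/√(β²+σ²) = 0.518, i.e. a Gaussian rank correlation of
(6/π)·asin(ρ/2) ≈ 0.50; the tests confirm the pipeline's Spearman
estimate against a Monte-Carlo oracle on the latent model.

What the generator does **not** model: prompt-driven usage bursts (weekly
staff check-ins), within-window engagement drift, feature-level event
types, item-level response correlation beyond the common scale target,
or informative dropout (the hazard is engagement-independent). Passing
tests therefore show the *pipeline* is correct under the stated model,
not that the model captures any real cohort.

## Numerical and design choices

- Session duration uses `max(span, floor)` rather than `span + floor`:
  the floor is a lower bound for degenerate single-event sessions, not a
  per-session surcharge, so a 5-minute session contributes exactly 5
  minutes.
- The elbow tie-break (smallest τ) and the ≤ 0 fallback rule make
  threshold selection deterministic on every curve.
- All randomness descends from one `numpy` `SeedSequence`; per-participant
  event streams use spawned child generators, so cohorts are reproducible
  byte-for-byte and stable under config changes that do not touch the
  participant count.
- Pipeline runs write plain CSV/JSON only; the manifest echoes the config
  (minus the output directory) so two runs of one config+seed are
  byte-identical wherever they are written.
- Problem sizes in the test suite and acceptance script (n = 24–27 for
  calibration, n = 500 for recovery, 2,000 Monte-Carlo replicates,
  reduced events-per-session in bulk simulations) were chosen to give
  stable estimates — Monte-Carlo SE ≈ 0.005 on the type-I error, < 0.05
  on recovered correlations — at interactive runtimes.

## Known limitations

- NQ-2021 absolute scores depend on the stand-in weights (see above).
- The regularity rule is one defensible reading of "daily use with
  intervals of ≤ 7 hours"; cohorts generated under the default Poisson
  timing model rarely satisfy its strict daily-coverage + 2-sessions/day
  requirement, so the regularity stratum is often degenerate on synthetic
  data even though the machinery is fully exercised by construction in
  the tests.
- Exact Wilcoxon p-values are discrete; at n = 24 the achievable
  two-sided level just below .05 is ≈ .045–.05, so empirical type-I error
  sits slightly below nominal.
- No timezone database lookups are performed on event data; supply an
  IANA timezone if day boundaries other than UTC midnight matter.
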