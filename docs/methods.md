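# Methods

This note documents the model behind `weeklycoach`: the weekly
aggregation rules, the selection procedure and its constraints, the
synthetic-data generator, and the numerical and design choices that were
genuinely open.

## The weekly tailoring variables

All feedback is driven by eight variables computed per participant-week
from raw daily records (units: lbs, kcal, minutes):

1. **Weight change** over the past week — the window's weekly weight
   minus the previous window's. The weekly weight is the *last* weigh-in
   of the window by default (`weight_reduction="mean"` switches to the
   window mean). "Last" matches the semantics of a weekly check-in and is
   robust to sparse weighing; with one weigh-in per week the two
   coincide. The change is absent whenever either side has no weigh-in.
2. **Cumulative percent change** — `100 · (weekly weight − baseline) /
   baseline`, absent on weeks with no weigh-in. Baseline is the weight
   measured in program week 1, carried on the profile.
3. **Days self-weighed** — days with a weight present (intraday
   duplicates must be pre-reduced upstream; first-of-day by convention).
4. **Weekly MVPA minutes** — the sum of daily tracker minutes.
5. **Activity tracking days** — days with minutes present *and* > 0; a
   worn-but-idle day (0 minutes recorded) does not count as tracking.
6. **Average calorie intake** — mean over days with dietary records,
   absent if none.
7. **Days within / above / below the calorie range** — the range spans
   300 kcal below the participant's calorie goal up to the goal, both
   bounds inclusive. Days *below* the range are treated as likely intake
   underreporting, so dietary self-monitoring adherence
   (`monitoring_days`) counts only within-or-above days.
8. **App use** — whether the companion app was opened at all this week.

Weekly weight change is categorized as loss (< −0.4 lbs), maintenance
(−0.4 to 0.4 lbs, both endpoints inclusive), or gain (> 0.4 lbs); the
three categories partition the line, and an uncomputable change is
UNKNOWN. Week windows are anchored to the program start date (week *k*
covers days 7(k−1)…7k−1 after it), never to calendar weeks.

**Trailing trend.** Several rules reference "the three weeks prior to
last week", read here as program weeks k−4…k−2. The net trailing change
is the sum of the available weekly changes in that window (absent if all
three are absent) — the simplest missing-data rule that degrades
gracefully. The trend is also discretized to a six-level summary
(ALL_LOSS, ALL_GAIN, MIXED_LOSS, MIXED_GAIN, FLAT, UNKNOWN): categories
that all agree give the ALL levels; disagreeing categories are MIXED with
the sign taken from the net change through the same ±0.4 lbs band; no
observable weeks give UNKNOWN. The encoding is this package's convention
— the upstream system's exact discretization is not published.

**Milestones.** First-time 5% and 10% cumulative-loss milestones fire
when the unrounded cumulative percent change reaches −5 / −10 (compared
with ≤, no tolerance), at most once each per participant; one week can
fire both.

## Message selection

**Weight feedback.** On a week with at least one weigh-in, the criteria
signature is the tuple (weight category, trailing summary, cumulative
band, intent), with cumulative bands at (−∞,−10], (−10,−5], (−5,−2],
(−2,0], (0,∞) percent — a documented convention; bank criteria may also
compare the raw values. Messages matching the signature are gathered, ids
already sent at that signature are excluded, and the remainder is drawn
uniformly. When the signature's pool is exhausted the engine restarts
with the least-recently-sent id, which maximizes spacing between repeats
(the no-repeat guarantee only holds until the bank runs out). Zero
weigh-ins yield the self-weighing reminder instead of weight feedback;
behavioral feedback is still generated on such weeks (only the weight
component is replaced), with weight-dependent criteria evaluating against
absent values.

**Progress tier.** Theme probabilities are driven by a deterministic
three-level tier: DECLINING if the past week was a gain or the trailing
net change exceeds +0.4 lbs; IMPROVING if the past week was a loss and
the trailing net is below −0.4 lbs; FLAT otherwise. A week with UNKNOWN
weight category is always FLAT — with no current weight data there is no
basis for calling progress good or bad, even if the trailing window
suggests a direction. The tier construction and the per-tier theme
weights are configuration (they live in the bank file), so deployment-
specific values can be dropped in without code changes.

**Theme.** A weighted categorical draw over the bank's themes at the
current tier, with the previous week's theme zeroed out and the weights
renormalized. Bank validation requires at least two positively weighted
themes per tier, so the renormalized distribution is always proper and
the no-consecutive-repeat rule is always satisfiable.

**Parent subcomponent.** Among the theme's parents whose criteria match
the weekly state, those in the previous week's behavioral domain are
excluded and one of the rest is drawn uniformly. If the exclusion empties
the pool, the theme's fallback parents outside the excluded domain step
in; only if none exists is the domain repeat permitted, and that event is
flagged in the audit. Every theme must ship at least one fallback parent
(criteria nearly all participants meet — the shipped bank's fallbacks
have empty criteria), which is what makes the coverage guarantee
checkable.

**Targeted feedback.** If the parent's placeholder slot requests it, a
uniform draw among the bank's targeted messages matching (parent domain,
slot type), where type is reinforcement or strategy. The slot type is
authored per parent message.

**Rescue mode.** A profile flag that replaces the entire message with a
neutral check-in, rotated through the bank's check-in texts in order.
Bank validation rejects check-in texts containing numerals or
placeholders, so rescue output can never leak progress data. The weekly
variables are still computed and logged internally on rescue weeks so the
week sequence stays contiguous if the participant later resumes.

**Randomness.** Each participant-week gets its own RNG stream seeded by
SHA-256 of (global seed, participant id, week index), truncated below
2³¹. Results are therefore reproducible and independent of cohort
iteration order; builtin `hash` is avoided because it is
process-randomized.

## The criteria language and coverage checking

Criteria are conjunctions of atomic comparisons (`LT LE EQ GE GT IN
BETWEEN PRESENT ABSENT`) against a declared variable set; disjunction is
expressed as multiple bank entries. Comparing an absent optional value is
false (except `PRESENT`/`ABSENT`), so sparse weeks fall through to
low-data fallbacks rather than erroring. Unknown variable names fail at
bank load, never at match time.

`check_coverage` sweeps a discretized grid over the state space and
verifies that every (theme, state) pair has at least one eligible parent
and that every parent is reachable. The documented default grid takes
each count variable at 0/4/7 (the three calorie-day counts jointly
constrained to sum ≤ 7), MVPA at 0 / half the goal / twice the goal,
average intake absent / below / inside / above the range, every enum at
all levels with tied numeric representatives, and both intents —
435,456 states, swept in about ten seconds with early-exit matching. The
grid is a parameter, so tests compare findings against a brute-force
double loop on reduced grids.

Bank validation additionally enforces: unique ids; resolvable theme
references; at least **two** weight messages matching every reachable
criteria signature (evaluated over all 240 signature states with band
representatives), so the habituation rule always has an alternative; a
targeted message for every (domain, type) pair; and a whitelist for
template placeholders — only summary-box behavioral variables and goals
may be interpolated, never weight values, so behavioral texts cannot leak
weight feedback.

## The synthetic-data generator

`simulate_participant` draws weight on day *d* (1-based) as
`start + drift · d/7 + N(0, σ_day)`, so the last weigh-in of week *k*
sits exactly at `start + drift · k` when noise is zero — which puts the
closed-form 5% milestone for a 1 lb/week loser starting at 200 lbs
exactly at week 10. Calories are `max(0, N(μ_cal, σ_cal))`, activity
minutes `max(0, N(μ_mvpa, σ_mvpa))`, each emitted per-day with its own
Bernoulli adherence probability; app opens are scheduled per-week with
probability `p_app_open` on a uniform day.

Defaults describe a realistic remote-BWL participant: 220 lbs start,
−0.5 lbs/week drift, 1 lb day noise, 75% weigh-in, 70% logging and 80%
wear adherence, 1700 ± 300 kcal logged intake, 25 ± 15 activity minutes
per worn day, 60% weekly app-open probability.

What the generator deliberately does **not** emulate: autocorrelated or
plateauing weight dynamics, weekend/weekday adherence structure,
correlated missingness (e.g., disengagement affecting all streams at
once), measurement error that depends on weight, or reactive behavior
change after feedback. Passing tests therefore demonstrate the *engine's*
correctness — rule fidelity, constraint satisfaction, determinism,
coverage — not that the message content would be clinically effective or
that real cohorts resemble these trajectories.

Canned scenarios (`make_scenario`) are deterministic fixtures generated
by code with fixed per-name seeds — the function is the golden source,
and `coach simulate` regenerates the files on demand. The `regainer`
scenario scripts its weekly weigh-ins (200, 201, 200.2, 201.5, 201, 202,
…) so that week 6 lands exactly on the mixed-gains weight signature:
past-week gain, trailing categories a mix of gains and losses with net
gain, cumulative change positive.

## Numerical and rendering choices

Display rounding is half-away-from-zero (one decimal for percents,
integers for kcal and minutes) and applies only at render time; all
comparisons (±0.4 bands, milestone thresholds, range bounds) use
unrounded values. Absent fields render as fixed placeholder phrases
("no weigh-ins", "no dietary records"), never as zero. Category and band
boundaries are all inclusive on the side stated above; ties in the
least-recently-used reset break by bank order. Uniform draws map one
`random()` value to an index (floor of `u·k`), keeping audits to a single
recorded draw per stage.

## Known limitations

- The shipped message bank is an original default written for structure,
  not a clinically validated content set; deployments must supply their
  own. Theme weights per tier are likewise placeholder values.
- The ≥2-messages-per-signature check evaluates raw-valued weight
  criteria at band-representative points; a bank using raw thresholds
  that cut *within* a band could under-cover a sliver of it. The shipped
  bank keys on discretized fields only.
- Aggregation assumes one record per day; upstream systems with intraday
  weigh-ins must pre-reduce.
- History is mutated in place by `compose_week`; callers replaying weeks
  must start from a fresh or persisted history, not reuse one mid-state.
- The simulator's weight process is linear-drift-plus-noise and is not a
  physiological model.
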