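# weeklycoach

A rule-based engine for weekly automated coaching messages in behavioral
weight-loss (BWL) programs — the message-generation backbone of a
just-in-time adaptive intervention (JITAI).

Participants in remote BWL programs self-weigh daily, log dietary intake,
and wear an activity tracker. `weeklycoach` turns those daily
self-monitoring streams into one tailored coaching message per program
week, assembled from three components:

1. **Summary box** — the week's numbers: cumulative percent weight change
   from baseline, past-week status (lost / gained / maintained), average
   daily calorie intake against the target calorie range
   `(goal − 300, goal)` kcal, days in range, weekly MVPA (moderate-to-
   vigorous physical activity) minutes, activity-tracking days, and the
   weekly activity goal.
2. **Weight feedback** — a message drawn from a criteria-tagged bank keyed
   on the past-week weight category (loss < −0.4 lbs, maintenance
   −0.4…0.4 lbs, gain > 0.4 lbs), the trailing three-week trend, the
   cumulative percent-change band, and the participant's stated intent
   (lose vs maintain). The same message is never repeated at the same
   criteria signature until all alternatives are exhausted; first-time 5%
   and 10% weight-loss milestones prepend a congratulation; a week with no
   weigh-ins yields a self-weighing reminder instead.
3. **Behavioral feedback** — built in stages: a *theme* (tone category)
   drawn with probabilities set by the participant's progress tier and
   never repeated two weeks running; a *parent* subcomponent of that theme
   matched by data criteria, addressing exactly one behavioral
   prescription (self-weighing, dietary monitoring, calorie intake,
   physical activity, app use) and never the same prescription two weeks
   running; and optionally a domain-matched *targeted* closer
   (reinforcement or strategy tip).

A user-activated **rescue mode** replaces everything with a neutral
check-in that references no participant data. Every selection decision is
recorded in a machine-readable audit, and the whole pipeline is a pure
function of (inputs, seed). Message content lives in an external YAML
bank (a validated default ships with the package); the engine is the
machinery, the bank is configuration.

A synthetic-cohort simulator (linear weight drift + day noise, Bernoulli
adherence thinning per stream) makes the full pipeline runnable and
testable with no participant data.

## Worked example

```bash
coach simulate --scenario steady_loser -o demo/
coach run --records demo/steady_loser_records.csv \
          --profile demo/steady_loser_profile.yaml --week 5 --seed 2
```

prints the composed week-5 message:

```
Weight change since start: -2.6%
Past week: lost weight
Average daily calories: 1641 kcal
Target calorie range: 1500-1800 kcal
Days in calorie range: 6 of 7
MVPA minutes this week: 142
Activity tracking days: 5 of 7
Weekly activity goal: 150 minutes

Your weight came down this past week. Think about what went well for you
these last few days, and how you might carry it into next week.

You put together 6 days of dietary records this week. You are most of the
way to a complete week; one or two more logged days would give you the
full picture. Try pre-logging tomorrow's meals tonight; editing a plan is
easier than recalling a day.
```

The first block is the summary box: this simulated participant has lost
2.6% of baseline weight, lost weight in the past week, averaged 1641 kcal
per day against a 1500–1800 kcal target range, and logged 142 MVPA
minutes toward a 150-minute weekly goal. The second block is the weight
feedback chosen at the week's criteria signature; the third is the
behavioral component — here a "Steady Habits" parent about dietary
monitoring, closed by a strategy-type targeted message for the same
domain.

Other entry points:

```bash
coach trial --cohort cohort.yaml --weeks 52 --seed 42 -o out/   # full cohort
coach validate-bank my_bank.yaml                                # lint a bank
```

`coach trial` writes per-participant message logs, JSONL selection
audits, weekly variables tables, delivery manifests (noon on the day the
week closes), and a cohort report (theme usage and transitions, domain
transitions, milestone events, fallback counts).

As a library:

```python
import weeklycoach as wc

records, profile = wc.make_scenario("regainer")
bank = wc.load_bank()
history = wc.ParticipantHistory(participant_id=profile.participant_id)
for k in range(1, 7):
    window = wc.WeekWindow.for_week(profile.program_start, k)
    message = wc.compose_week(records, window, profile, history, bank,
                              global_seed=42)
print(wc.render_message(message))
```

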