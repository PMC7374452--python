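# qsrec

Quantified-self user modelling and context-aware activity recommendation for
childhood-obesity interventions, plus the summary-statistics machinery used to
validate such programs.

Gamified health programs for children aged 6–12 with obesity (BMI at or above
the 95th-percentile reference for sex and age) collect a *quantified-self* (QS)
record per child — anthropometrics, wearable biometrics, per-session emotions,
diet adherence, standardized behavioural scores, a gamification player
typology, schedules and locations — and use it to decide **when** to recommend
an activity and **what** to recommend. `qsrec` implements that pipeline as a
tested library:

- **`qsrec.user_model`** — the multidimensional QS record with derived
  indicators (BMI, obesity class against growth-chart thresholds, sedentary
  minutes, KIDMED diet tier, HEXAD dominant player type, emotion valence) and
  append-only ingestion that reports which indicators changed.
- **`qsrec.triggers`** — when to recommend: weekly-schedule slots, geofenced
  places (haversine distances), and edge-triggered QS-model changes; each
  firing carries a *trigger goal* (variables with desired directions).
- **`qsrec.planner`** — what may be recommended: actions with binary-clause
  preconditions and goal effects, context-aware filtering against the trigger
  goal, and construction of multi-step *plans* whose stepwise preconditions are
  guaranteed by their predecessors' effects.
- **`qsrec.bandit`** — which action to send: a contextual multi-armed bandit
  (UCB1 by default, epsilon-greedy available) over coarse context keys
  (time-of-day bin × weekday/weekend × location category × player type),
  learning from reward feedback with sublinear cumulative regret.
- **`qsrec.simulate`** — a synthetic cohort simulator closing the
  trigger → filter → choose → reward loop, with latent per-category
  preferences driving Bernoulli rewards, session emotion dynamics, and a
  pirate-themed gamification ledger (points, missions, islands).
- **`qsrec.stats`** — one-way ANOVA reconstructed from group summaries (F,
  partial eta squared η²p = SSb/(SSb+SSw), SPSS-style observed power),
  chi-square goodness of fit, Fleiss' kappa with Fleiss/Altman interpretation
  bands, paired t with effect size, Bonferroni adjustment, and emotion-valence
  transition tables.

The chooser is a UCB1 bandit: in context *c*, an untried arm is pulled first;
otherwise the arm maximizing *μ̂ᵢ + c·√(2·ln N / nᵢ)* is chosen, where *μ̂ᵢ*
and *nᵢ* are the arm's empirical mean reward and pull count and *N* the total
pulls in that context.

## Worked example

Simulate a 45-child cohort (ages 6–12, all above the obesity threshold, 25
girls / 20 boys) for two weeks and learn per-child preferences online:

```python
from qsrec.simulate import SimConfig, run_closed_loop

result = run_closed_loop(SimConfig(n_children=45, n_days=14, seed=7))
m = result.metrics
print(m["n_events"], m["cumulative_reward"], round(m["mean_reward"], 3),
      round(m["cumulative_regret"], 2))
# 810 609.0 0.752 99.53
print(m["gamification"]["child_000"])
# {'points': 160, 'missions_completed': 16, 'islands_unlocked': 3}
```

810 recommendations fired over the two weeks; 609 earned a positive response
(mean reward 0.752), and the cumulative regret — the shortfall against an
oracle that always picks each child's truly preferred candidate — is 99.5,
i.e. ~0.12 per recommendation while the bandits are still exploring. The first
child completed 16 missions (160 points) and unlocked 3 pirate islands.

The same run is available from the shell, writing a CSV event log and JSON
metrics that are byte-identical for a fixed seed:

```sh
qsrec simulate --out run/ --seed 7
qsrec stats anova-summary --groups groups.csv   # columns n, mean, sd
qsrec stats kappa --ratings ratings.csv
qsrec stats chi2 --observed 50,30,20
```

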