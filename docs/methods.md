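# Methods

## The recommendation pipeline

The library models a behaviour-change recommender for children with obesity as
three cooperating decisions over a quantified-self (QS) user record.

**When to recommend (triggers).** A recommendation can fire because the weekly
schedule reaches a configured slot, because the child is within a geofence
radius of a place of a configured category (great-circle distance on a sphere
of radius 6,371,000 m), or because ingesting a record changed a derived QS
indicator past a threshold. Model-change rules are *edge-triggered*: they fire
only when the indicator appears in the ingestion change set, never merely
because the condition keeps holding — otherwise a child sitting still would be
nagged every minute. Each rule also has a refractory period (default 60
minutes; the underlying study describes no deduplication policy, so this is a
library decision, configurable per rule). Every firing carries a *trigger
goal*: the variables that caused it, each with a desired direction
(increase / decrease / maintain).

**What may be recommended (action filter and plans).** Catalog actions declare
preconditions as binary clauses (one comparator over one state variable) and
goals as effects (set / increase / decrease on a variable). The world state is
closed: a clause over an absent variable is false, so nothing is recommended
on unknown state — the conservative choice when the unknown variable may be
safety-relevant. An action passes the filter when all its preconditions hold
and at least one of its effects *addresses* a goal target; the
direction-compatibility map (increase ↔ {set, increase}, decrease ↔ {set,
decrease}, maintain ↔ {set}) is itself configuration, since "addresses" is a
modelling choice. Plans are ordered sequences of distinct actions in which
each step's preconditions hold in the state produced by its predecessors and
whose combined effects cover the goal; by default a plan must address *all*
goal targets (configurable — covering at least one is the weaker reading).
Plan search is a depth-bounded exhaustive walk over no-repeat action
sequences (default depth 3). At catalog scale — a handful of actions, short
plans — the sequence space is tiny, and exhaustive search is the only strategy
that is provably identical to brute-force enumeration; state-based pruning
would drop valid orderings that revisit a world state by different routes.

**Which to send (contextual bandit).** The chooser treats each coarse context
key — time-of-day bin over half-open ranges [6,12), [12,18), [18,24), [0,6);
weekday vs weekend; location category; HEXAD dominant player type — as an
independent bandit table; the context is deliberately a coarse approximation
and no generalization is attempted across keys. The default policy is UCB1
with exploration constant c = 1 (configurable): untried arms first
(lexicographically smallest), then argmax of mean + c·sqrt(2·ln N / pulls),
ties to the smallest action id so replays are exact. Epsilon-greedy is
provided behind the same interface. Rewards live in [0, 1]; arm means are
updated by the incremental running mean. The reward signal itself is not
defined by the source study; the simulator uses the Bernoulli outcome of the
child's latent preference, and an exit-emotion mapping (positive → 1.0,
neutral → 0.5, negative → 0.0) is the documented alternative.

## QS user model conventions

- BMI is weight/height²; obesity is BMI ≥ the sex/age threshold of the shipped
  growth-chart reference table (printed points at ages 8.5 and 9.5 per sex),
  linearly interpolated between tabulated ages and clamped outside them. The
  cohort inclusion criterion "above the 95th percentile" is operationalized as
  exactly this threshold test; full percentile curves are out of scope. The
  published medians exist only at age 8.5 and are carried as optional
  metadata, not used for classification.
- Diet adherence uses the standard 16-item +1/−1 questionnaire scheme with
  tiers ≤3 low, 4–7 medium, ≥8 high (all configurable); the instrument's exact
  item text is proprietary and not modelled.
- Behavioural scales flag "at risk" at standardized scores ≥60 (<70) for
  difficulty scales and ≤40 (>30) for adaptive scales; "clinical" at ≥70 and
  ≤30 respectively.
- The HEXAD dominant type is the maximum subscale, ties broken by the fixed
  order Philanthropic, Achiever, Socializer, Free spirit, Player, Disruptor.
- Sedentary time counts minutes in a half-open window whose per-minute step
  rate is below threshold (default 20 steps/min); minutes with no samples
  count as sedentary — conservative for triggering, and configurable.
- Timestamps are timezone-aware (naive input is taken as UTC); all windows and
  schedule slots are half-open [start, end). Histories are append-only and
  strictly time-ordered; re-ingesting the exact last record is a no-op, which
  reconciles idempotent replay with strict ordering.
- The emotion label set is a 10-label stand-in with a configurable
  label → valence map; the instrument's actual label inventory is not
  published.

## The cohort simulator

The generator emulates the study population rather than any deposited data:
45 children by default (25 girls, 20 boys), ages uniform on [6, 12], heights
near the reference medians, and BMI drawn strictly above the sex/age obesity
threshold (threshold + 0.1 + Gamma(2, 1)), so every child satisfies the
inclusion criterion by construction. Each child carries a latent preference
per action category — Beta-distributed around configurable base means
(defaults 0.8 active games, 0.6 physical activity, 0.55 motivation, 0.45
nutrition education, 0.35 reminders; concentration 5) — which drives Bernoulli
reward feedback. These bases are the simplest identifiable reward model that
makes bandit learning testable; nothing in the source study fits one.

Session emotions follow a first-order transition matrix over
positive/negative/neutral whose default rows encode the observed session
percentages (neutral → positive 1.0; negative → positive 0.8, → neutral 0.2;
positive → positive 0.944, → negative 0.043, → neutral 0.013). Treating those
aggregate percentages as per-session probabilities is an emulation choice, not
a claim that such a chain was fitted. The child's entrance emotion is the exit
emotion of the previous session.

A simulated week offers a daily after-school slot (17:00–18:00) plus a weekend
morning slot (10:00–11:00 Sat/Sun) — two trigger opportunities on weekend
days, one on weekdays — keeping full runs desk-scale (a 45-child, 14-day run
is under a second; the parameter-recovery analyses use 2 children × 1946 days,
about 5,000 events, a few seconds). Completed recommendations (reward 1) feed
a pirate-themed ledger: 10 points per mission, an island unlocked every 5
missions, all monotone over a run.

Each child gets an independent bandit by default (`share_bandit` pools them);
regret is computed against the oracle that always picks the candidate with the
highest latent preference in the child's context. All randomness descends from
one seed via spawned generators, so runs (and their CSV/JSON outputs) are
byte-reproducible; bandit state serializes to JSON and is exactly
reconstructable by replaying the feedback log.

What passing simulations do **not** show: the generator has no physiological
realism (no energy expenditure or growth), no sensor noise, no real map data,
and stationary latent preferences; results on it demonstrate the pipeline's
correctness and the learner's behaviour under the stated reward model, not
clinical effectiveness.

## Statistics

`anova_from_summary` reconstructs one-way ANOVA exactly from per-group
(n, mean, SD): SSb = Σ nᵢ(mᵢ − m̄)², SSw = Σ (nᵢ−1)sᵢ², F with (k−1, N−k)
degrees of freedom, η²p = SSb/(SSb+SSw). Observed power follows the SPSS
convention — the upper-tail probability of the noncentral F with
noncentrality λ = F·df_between at the α = 0.05 central critical value — which
reproduces all three printed baseline power values (0.25, 0.10, 0.11); λ
conventions differ across packages, so this one is stated explicitly. The
printed baseline F of 1.75 reconstructs as 1.7553 from the rounded published
summaries (the original was computed from raw scores), hence comparisons are
made at two-decimal resolution. Group SDs use divisor n−1.

Fleiss' kappa is computed via statsmodels' implementation with the band labels
attached here: Fleiss — poor below 0.40, intermediate-good 0.40–0.75,
excellent above 0.75; Altman — poor ≤0.20, fair ≤0.40, moderate ≤0.60, good
≤0.80, very good above. Chi-square goodness of fit uses no continuity
correction and rescales expected proportions to the observed total. The paired
effect size is d = mean(diff)/SD(diff); published paired d values computed
under an unstated convention (1.2, 0.99) are not reproducible from printed
summaries and are deliberately not asserted anywhere. Bonferroni is
min(1, m·p).

Degenerate inputs raise typed errors rather than returning NaN: zero
within- and between-group variation, single-category chi-square (df 0),
zero-variance paired differences, expected agreement of 1 in kappa.

## Numerical and testing choices

- Exact-equivalence properties (planner vs brute force, summary ANOVA vs
  direct ANOVA on data reconstructed to have exactly the stated mean/SD) are
  asserted to 1e−9 (relative for large F); reference statistics are compared
  at the precision they are printed.
- The ANOVA oracle reconstructs each group by standardizing a fixed base
  vector, giving data with exactly the requested mean and sample SD to machine
  precision.
- Stochastic checks (bandit regret, Monte-Carlo transition recovery) run on
  fixed seeds at the sizes stated above, with bounds derived from the binomial
  sampling error of the quantity being recovered.
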