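# Methods

## Data model and eligibility

The unit of evidence is a decided dyadic agonistic interaction: a dated
winner/loser pair of one of two low-intensity types, displacement or
avoidance. Aggression records are never admitted to rating — its
expression depends on context and incentives and does not reliably
express an established dominance relationship the way ritualized,
decided interactions do. Each individual's membership in a group's
hierarchy is an inclusive presence window `[entry_date, exit_date]`
from the life-history table; interactions on the entry or exit day
itself are admitted, and the validation report flags this convention.
Entry classes are `start` (present at study start), `N` (natal female
reaching maturity), `IN` (nulliparous immigrant), `IP` (parous
immigrant); exits are death, emigration, fission, study end, or
censoring.

Eligibility keeps adult females only: at least 8 years old for mountain
gorillas and 10 for western gorillas, with the threshold overridable
for other systems. Individuals with unknown age are retained: parous
immigrants and present-at-start females are adult by definition or have
age estimates too inaccurate to act on, and for `N`/`IN` entrants the
hierarchy-entry event itself marks adulthood.

Groups whose interaction record is too sparse to support a hierarchy at
all are excluded before inference. The field rule is qualitative (a
few interactions per year over many years is not enough); this package
makes it explicit with a default threshold of 50 recorded interactions,
always surfaced in the inclusion report and overridable.

## Sequential Elo rating

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `k` | 100 | score transfer scale per interaction (equal intensity for all records) |
| `initial_score_start` | 1000 | score of individuals present at study start |
| `prob_model` | `logistic` | winning-probability curve; `normal` (Gaussian CDF, scale 200·√2) available |
| `entry_rule` | `lowest_current` | entrants receive the day's lowest current score |

The winning-probability formula behind the original long-term-study
analyses is a convention choice, and both common forms coexist in the
animal-dominance literature; both are implemented and the choice is
recorded in every run summary, so a replication can be run under
either. The two curves give `p = 0.5` at equal scores and are
complementary under swapping opponents; results on well-separated
hierarchies are insensitive to the choice.

Within a day, interactions are processed in file order — daily
timestamps carry no finer resolution, so file order is the only
same-day order there is (and it is therefore significant; permuting
records across *different* dates has no effect, which is property-
tested). Entrants are scored before any same-day interaction; exits
take effect at the end of the exit day. Scores carry forward unchanged
across gap days with no decay. Daily ordinal ranks order individuals by
descending score with ties broken by entry-date seniority (the earlier
entrant ranks higher), then identifier, so every table is
deterministic.

## Maximum-likelihood rating

The fitted variant treats `k` and the per-individual entry scores as
free parameters of a Bernoulli sequence model: replay the interactions
from the candidate entry scores at the candidate `k` and sum
`log p(observed winner)` over interactions, each `p` evaluated from
pre-interaction scores. Numerical choices:

- **Identifiability.** The likelihood is invariant to translating all
  entry scores, so fitted scores are constrained to sum to zero
  (optimization over `n − 1` free scores). Negative fitted scores for
  low-ranking individuals are expected and legal.
- **Positivity of `k`.** `k = exp(θ)`; `θ` is bounded in
  `[log 1e-6, log 5e3]`. A fitted `k` below 1e-3 is summarized as
  "virtually 0" with the raw value retained: it means the entry scores
  alone explain the outcomes and the sequence contributes no dynamics.
- **Optimizer.** L-BFGS-B with numeric gradients, multi-start: one
  start from centered traditional-Elo final scores at `k = 100`, one
  from flat scores, one from near-zero `k`, plus seeded jittered
  restarts (fixed internal seed; fits are bit-reproducible). The best
  likelihood wins; candidates within 1e-3 log-likelihood of the best
  are ties, broken in favour of the smallest `k`, so a `k` that buys
  nothing is reported at its boundary rather than at an arbitrary
  plateau value. Entry scores are optimized in units of 100 points with
  bounds ±6000: wide enough that perfectly separable (never-violated)
  orders can reach near-zero log-likelihood, which is what makes the
  boundary `k` the reported optimum in that regime.
- **Admissibility.** An individual who never wins (or never loses) has
  no finite-score optimum, so the fit requires at least one of each.
  Loss-only individuals receive one audited dummy win over the
  lowest-ranking female of the hierarchy fitted without them, dated one
  day after the group's last real interaction (clamped to the
  individual's window); win-only individuals — which arise in synthetic
  noise-free data where the alpha never loses — receive the symmetric
  dummy loss to the pass-1 top female. Dummies carry `is_dummy = true`,
  are listed in the audit log, and do not change the fitted ordinal
  relations among the other females (asserted in tests). Individuals
  with no interactions at all are excluded and reported.
- **Mid-study entrants** take their fitted entry score from their entry
  date; they have no score before entry.
- The inner likelihood replay is JIT-compiled when numba is available;
  a pure-Python implementation of the identical arithmetic is the
  fallback. Results are identical to double precision.

At 6 individuals, `k` is weakly identified below roughly 500
interactions: the boundary `k = 0` model, with `n − 1` free scores,
explains short sequences as well as the dynamic model surprisingly
often. Parameter-recovery checks therefore use 500-interaction
replicates (median fitted `k` within 10–15% of the generating value
over 50 replicates; at 300 interactions about a quarter of replicates
sit at the boundary and the median degrades to ~20%).

## Stability index

For each consecutive-day pair, ranks are recomputed among the
individuals present on both days; the day's churn is
`Σ_i w(r_i) |Δr_i|` with weight `w(r) = (N − r + 1)/N` at the earlier
day's rank, normalized by the same-weighted churn of a complete
reversal; `S` is one minus the ratio of summed observed to summed
maximum churn. The two endpoints are fixed by definition — constant
order gives `S = 1`, complete reversal every other day gives `S = 0` —
and the interior weighting (changes near the top count more) is this
package's documented choice; an unweighted variant (`w ≡ 1`) is
computed alongside for sensitivity. Because ranks are recomputed within
the common set, days whose only change is renumbering after an exit or
an entry contribute exactly zero: passive demographic turnover is not
instability.

## Mobility classification

Between consecutive days, the relative order among individuals present
on both days is compared. A change of relative order is **active** and
must coincide with at least one interaction on the later day — under
sequential rating nothing else can reorder co-present individuals, so a
violation raises an internal-consistency error. An absolute rank change
with relative order preserved is renumbering: **passive** when
explained by the exit of a higher-ranked female (the event names her as
trigger), and silent when explained by an entrant slotting in above
(entries are reported separately in the entry-rank report, not as
mobility). Days with both an exit and interactions resolve per
individual to the minimal explanation: passive if her relative order
among survivors is unchanged, active otherwise.

Dyad-level accounting covers every female pair with overlapping
presence (co-residence measured in 365.25-day years). The pair's
dominance direction on a day is the sign of their score difference,
with zero-difference days carrying the last nonzero direction (no
phantom reversals from ties). A **counted active reversal** requires an
interaction between the two whose winner contradicts the previously
established direction *and* whose outcome leaves the winner scored
above the loser at the end of that day; the direction is first
established by the earliest interaction between the pair whose outcome
agrees with their score order (a lone opening upset does not define a
relationship to reverse from). Score crossings induced purely by
third-party interactions, and upsets that do not overturn the pair's
order, are reported as unconfirmed flips but not counted: sequential
ratings of near-tied individuals cross constantly for reasons that are
not dominance reversals. Pairs never separated by a real interaction
are flagged undecided while still reporting a score-based direction.

Because the traditional entry rule places every entrant at the bottom,
non-bottom hierarchy entry is only observable under the fitted entry
scores; the entry-rank report therefore carries the method label, and
the pipeline emits the report under both parameterizations.

## Synthetic data

The generator emulates the structure the analysis assumes: 2–8 adult
females observed 7–17 years; decided interactions arriving as a Poisson
process at 3.6–20.4 per group-year, each drawn over a uniform co-present
dyad; a latent order that the winner respects with probability
`latent_steepness` (default 0.95, i.e. a steep but not deterministic
hierarchy); scripted entries (natal/immigrant, with a latent entry
position — immigrants need not enter at the bottom), exits (death,
emigration, fission) and injected latent-order swaps; everything
reproducible from one seed per dataset. Ground truth records the latent
order over time, the injected reversal dyads, each removal's implied
passive improvements, and each entrant's latent position.

What it deliberately does not model: affiliation or kin structure in
partner choice, male intervention, age or body-size covariates,
observation-effort variation, and winner/loser effects. Passing the
recovery tests therefore shows the inference machinery is correct under
the model's own assumptions — not that field data satisfy those
assumptions. The paper-shaped suite (`make_paper_like_suite`) fixes
four group configurations spanning the regimes above, including one
sparse group that exercises the inclusion check; the noise-free
scenarios (`stable_scenario`, `reversal_scenario`) use steepness 1 and
~25 interactions/year so that every dyad is repeatedly observed and
ground-truth recovery must be exact.

## Problem sizes and determinism

Acceptance-scale runs use the four-group suite (~430 interactions over
42 group-years), two 5-female noise-free scenarios, and 50
parameter-recovery replicates of 500 interactions each; the whole
recomputation takes well under a minute on one core. All randomness
flows from a single seed through `numpy.random.SeedSequence` spawning;
reruns are byte-identical.

## Known limitations

- The stability index's interior weighting is a documented convention;
  other weightings interpolate the same endpoints differently, so
  cross-study comparison of interior `S` values requires matching
  definitions (the unweighted variant is reported for this reason).
- The fitted `k` is only weakly identified in short sequences, and in
  separable (never-violated) sequences the likelihood surface is a
  plateau in `k`; the smallest-`k` tie-break makes the reported optimum
  well-defined but is itself a convention.
- Same-day interaction order follows file order; datasets whose within-
  day order is not meaningful should not encode information there.
- Dyadic reversal counting is deliberately conservative (it requires a
  confirming dyadic interaction); a genuine reversal between females
  who never interact again is reported only as an unconfirmed flip.
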