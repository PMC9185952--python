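# Methods

`denialsim` is a discrete-time (annual) agent-based model of firearm
homicide and suicide in a synthetic urban adult population, built to
evaluate firearm purchase-denial policies triggered by substance-related
contact with the criminal justice system.  This note documents the model,
its parameterization, the calibration procedure, the experiment design,
and the numerical choices, in enough detail to reason about what the
package's outputs do and do not show.

## The model

### Population and space

The full-scale population is 800,000 agents aged 18–84 at initialization,
representing roughly a 15% sample of a large city's adult population.
Agents live on a single rectangular lattice partitioned into 59
rectangular neighborhood blocks with areas proportional to population
shares (equal by default).  Multiple agents can share a cell; the default
density is five agents per cell, and the grid side scales with the square
root of the population so that distances measured in cells mean the same
thing at every scale.  Distances are Chebyshev (square radii), matching
the usual grid-neighborhood semantics of lattice ABMs; Euclidean is
available via `distance_metric`.

Agent attributes cover demographics (age, sex, race/ethnicity, household
income, education, partnership status), substance use (drinking status
none/light-moderate/heavy, alcohol use disorder, drug use, drug use
disorder), seven mental disorders (antisocial behavior disorder, GAD,
IED, MDD, mania, PTSD, psychosis), mental-health treatment, suicidality
histories, firearm states (legal ownership; carrying, which proxies
access to an illicit or informal firearm and does not require ownership),
violence histories (victimization, perpetration, and their IPV forms),
justice histories (four arrest types, convictions, permanent felony
status, incarceration), residential tenure, and the prohibition clock.

### Behavior equations

Every behavior and outcome probability is logistic in named predictors:
`P = expit(intercept + Σ coefficient × feature)`.  The logit link is a
deliberate design choice: it keeps every probability in [0, 1] for any
finite coefficients and makes calibration an additive adjustment of the
intercept.  The coefficient tables bundled as defaults are synthetic.
The survey-derived regressions behind the original model of this kind
were never published, so the defaults encode the documented qualitative
structure — heavy drinking, drug use, use disorders, prior victimization
and perpetration, arrest history, and firearm carrying raise violence
risk; suicidality tracks depression, substance use disorders, and its own
history; ownership history predicts ownership and current ownership
predicts carrying; arrest probabilities concentrate on current substance
users — and leave the levels to calibration.  Magnitudes were fixed once,
by two structural requirements: each process must be *stationary* against
demographic turnover (self-excitation weak enough that incidence settles,
at roughly 1.5 violent incidents per 100 person-years), and persistence
must be strong where the state is durable in reality (ownership is an
entry/exit process dominated by last year's state; mental disorders are
chronic via self-persistence terms).

One equation deserves its own justification.  The completed-suicide
equation includes current firearm ownership (+1.0 on the logit scale) and
carrying (+0.5) as lethal-means terms, in addition to demographic,
substance, and suicidality-history predictors.  Ready access to a firearm
is the canonical risk factor for a suicidal crisis ending in death, and
it is the causal channel through which removing a purchased firearm can
reduce suicide mortality rather than only relabeling deaths as
non-firearm.  Without it, a denial policy could only change the
*attribution* of suicides, which is bounded by the share of decedents
whose sole access was their own purchase — a few percent here, because
social-network access is common (with a mean of five close ties and ~22%
ownership, most agents can reach some firearm).

### Annual schedule

Each year runs seven ordered modules:

1. **Aging** — everyone ages one year (no upper bound).
2. **Death and rebirth** — all-cause mortality from a configurable
   age×sex schedule (default: a smooth synthetic Gompertz curve, female
   q(18)=4.0e-4 and male 6.5e-4 doubling every ~10 years, for a crude
   adult death rate near 1.2%/year).  Each decedent is immediately
   replaced by an 18-year-old with fresh demographics, empty histories,
   the same cell, and the same social-tie slots, keeping population size
   and the degree distribution stationary.
3. **Characteristics** — drinking status (two logistic probabilities
   with the residual as non-drinker), alcohol use disorder (drinkers
   only), drug use, drug use disorder (users only), the seven mental
   disorders, treatment, suicidal ideation and attempt (history flags),
   then firearm ownership and, given current ownership, carrying.
   Ownership is forced off for felons, actively prohibited agents, and
   the incarcerated.  All equations read one pre-update snapshot
   (synchronous update); the two exceptions, documented because the model
   structure demands them, are the use-disorder conditioning on *current*
   use and carrying reading *current* ownership.
4. **Movement** — relocation probability from income, residential
   tenure, and last year's victimization; movers draw a uniformly random
   different neighborhood and cell and reset tenure.
5. **Risk sets** — potential perpetrators and victims (non-IPV and IPV),
   potential homicide victims, and suicide deaths are drawn from their
   equations.  Suicide and homicide-victim probabilities are multiplied,
   on the odds scale, by `1 + w·(any tie ever involved in gun violence)`
   with `w = network_influence_weight` (default 0.15).
6. **Incidents** — potential perpetrators, in random order, search a
   15-cell square radius for the nearest not-yet-victimized potential
   victim; a victim with a police officer within 2 cells is protected.
   Each victim is victimized at most once per step.  IPV incidents are
   matched the same way among partnered agents.  An incident is a
   homicide when the victim is in the potential-homicide-victim set; a
   homicide or suicide is firearm-related when the perpetrator or victim
   (or the decedent) owns, carries, or can reach a firearm through a
   social tie.  The source is recorded with precedence ownership >
   carrying > network (reporting only).  That a death counts as
   firearm-related when only the victim had access is the attribution
   convention of this model family; it can be switched off
   (`victim_access_counts`).
7. **Justice and policy** — sentences decrement (release at zero); four
   arrest types are drawn per agent; each arrest is charged misdemeanor
   vs felony (type-level split), then convicted or not (agent
   demographics, a borough-proxy covariate, the charge class, and a
   per-type calibrated offset).  A felony conviction sets the permanent
   ownership ban, removes any owned firearm, and draws incarceration
   with sentence length `(1 + Poisson(1)) × (1 + w·gun-violence
   exposure)`.  Finally the policy bookkeeping runs: per-criterion event
   recency is updated for all criteria (so "ever qualified" subgroups
   are defined in every scenario), and the active policy, if any,
   prohibits qualifying agents.

Agents killed by homicide or suicide are replaced at the end of the same
step, so population size is exactly constant at every step boundary.
Incarcerated agents skip movement, the violence pool, arrests, ownership,
and carrying.

Each module draws from its own named random stream (one generator per
module, seeded from the master seed), so extra draws in one module never
perturb another module's sequence — the basis of the common-random-number
scenario comparisons.

### Social network

Each agent draws a target degree from U{1..9} (mean 5, the familiar
"close friends" count).  Ties form by stochastic candidate sampling: a
pool of candidate pairs (part same-neighborhood, part global) is scored
by weighted similarity — age closeness, same sex, race/ethnicity,
education, ownership status, drinking status, drug use, and spatial
proximity — and accepted greedily from the best score down while both
endpoints have spare capacity; a cleanup pass pairs leftover stubs so the
realized mean degree stays at 5.  Ownership similarity carries one of
the largest weights, so firearm access clusters — without it, nearly
every agent would have network access to a firearm and denial policies
could not bite.  The network is fixed for the whole run; rebirth agents
inherit tie slots.

### Policies

Twelve interventions: four criteria (alcohol-related misdemeanor
conviction, alcohol-related arrest, drug-related misdemeanor conviction,
drug-related arrest) × three forms (one event / 5-year prohibition, one
event / 10-year, two events of the same kind within a 5-year window /
10-year).  "Within a 5-year period" is implemented as a year gap of at
most 4 inclusive (events in years t and t+4 qualify; configurable to 5
via `two_event_max_gap`).  Qualification removes any owned firearm at
once and blocks legal purchase for years t+1..t+duration; carrying is
untouched; re-qualification resets the window; the felony ban dominates.
The policy is active during burn-in as well, so reported contrasts
reflect its steady state.  Enforcement is perfect by construction, so
estimated effects are upper bounds.

## Calibration

Eight statistics are calibrated to empirical annualized targets: firearm
homicide 3.96 and firearm suicide 0.98 per 100,000; alcohol-related
misdemeanor convictions 116.1, alcohol-related arrests 134.9,
drug-related misdemeanor convictions 525.7, and drug-related arrests
1,329.1 per 100,000; firearm ownership 22.03% and carrying 3.94%.  Each
statistic maps to one adjustable intercept (the homicide-victim,
suicide-death, two arrest, ownership, and carrying equations, plus the
two per-type conviction offsets).  Each iteration simulates two
replications with fixed seeds (common random numbers across iterations),
measures the statistics, and applies a damped simultaneous update on the
logit scale, `intercept += λ·(logit p_target − logit p_sim)` with
λ = 0.5, updates clamped to ±2; convergence is all relative errors ≤ 2%
(default), with a cap of 40 iterations.  On a noise-free single-target
model this iteration is exactly contractive for λ ≤ 1, which the test
suite verifies against the closed form.

Two variance-reduction choices make the 2% stopping rule meaningful:

- **Rao-Blackwellized statistics.**  Rates are measured as sums of
  per-agent event probabilities given the simulated state (for firearm
  suicide, Σ p_suicide × has-access; for convictions,
  Σ p_arrest·p_misdemeanor·p_conviction), not realized Bernoulli counts.
  Both estimate the same rate — the tower property guarantees equal
  expectations, and the reporting path (`summarize_rates`) uses realized
  counts so the equality is observable — but a firearm-suicide rate near
  1/100,000 realizes only ~15 events per 50,000-agent replication (26%
  noise), against well under 1% for the conditional expectation.
- **A measurement window matching the reporting window** (10 burn-in +
  30 observed years).  Ever-history prevalences equilibrate on a
  decades-long timescale; initializing histories from the
  lifetime-exposure approximation `P(history) = 1 − (1 − p_annual)^(age−18)`
  puts the initial population near its stationary age profile, and
  matching windows absorbs the residual drift.

At 50,000 agents the full calibration converges in well under 15
iterations and a few minutes on one CPU.

## Experiments

Each scenario runs as independent replications (default at full scale:
100 × 30 years after 10 burn-in years; the acceptance pipeline uses 20–30
replications at 1/16–1/32 scale).  Baseline and interventions share
derived per-replication seeds, so percent decreases,
`(baseline − intervention)/baseline × 100`, are matched-pair contrasts;
negative values are legitimate.  Confidence intervals are normal
approximations, mean ± 1.96·SD/√n across replications, with a percentile
bootstrap available.  Subgroup ("high-risk") rates restrict person-years
and firearm deaths to agents from their first qualification onward.
Directional property tests use the Rao-Blackwellized firearm death rates
(homicide + suicide combined, matching how the interventions' purpose is
phrased) because paired differences of the realized counts at desk scale
are dominated by Poisson noise.

The sensitivity suite re-runs the analyses under three variants: firearm
ownership recalibrated to a halved 11% target, and network influence
weight set to 0.10 and 0.25.

## What the synthetic data does and does not show

The generator emulates the *structure* of the study system: co-occurring
substance use, psychiatric morbidity, violence, suicidality, and justice
contact; homophilous social clustering of firearm access; spatially
matched violence with police protection; and justice-triggered
disqualification dynamics, calibrated so the eight headline rates match
their empirical targets.  It does not estimate real covariate effects:
coefficient magnitudes are stylized, geography is a uniform lattice (not
a real city's districts), demographic marginals are generic urban values
rather than census tables, and the illicit-market proxy (carrying) is
calibrated only at the prevalence level.  Passing tests therefore
establish that the mechanisms are implemented correctly and that the
policy conclusions are directionally robust within this model family —
not that the effect sizes transfer to any real jurisdiction.  Exact
published intervention percentages depend on unpublished survey-derived
coefficients and are treated as order-of-magnitude references only.

## Numerical and implementation notes

- Agents are stored struct-of-arrays; all per-year equation evaluations
  are vectorized.  Feature extraction is a lazy snapshot view: each
  pipeline stage materializes only the predictors its tables reference,
  and stages that mutate state they also read snapshot those predictors
  first.
- Spatial queries (victim search, police protection) use a k-d tree with
  the Chebyshev metric; the radius bound is made inclusive by querying at
  radius + 0.5, exact for integer cell coordinates.  Victim ties at equal
  distance break uniformly via a random shuffle of the victim array.
- Police positions are redrawn each year in "waves" (one officer per
  neighborhood per wave), so configurations with more officers place a
  superset of the officers of configurations with fewer under the same
  seed — this makes protection monotonicity testable exactly.
- Greedy matching is provably monotone here: removing available victims
  (police protection) can never increase the matched count, and widening
  the radius can never decrease it; both are regression-tested per seed.
- Sentinel year −10⁶ encodes "never happened" in event-recency arrays.
- Degenerate inputs: an empty subgroup yields NaN rates with a warning
  (undefined, not zero); `n_runs < 2` is rejected (no CI); a probability
  pair from the drinking equations summing above 1 is renormalized.
- Determinism: every run is a pure function of (parameters, seed); the
  CLI writes a manifest (config hash, seed, version) sufficient for exact
  re-execution, and byte-identical reruns are tested.

## Known limitations

- The IPV channel shares the general matching radius and does not model
  partnerships explicitly beyond the partnered state.
- Conviction types are modeled as {misdemeanor, felony} × four arrest
  types (eight cells); reported statistics use the type-level rollups,
  and only the alcohol/drug misdemeanor cells are calibrated.
- Prohibited agents' removed firearms are also removed from their ties'
  network access; the alternative (household access persisting) is not
  modeled.
- Rebirth at age 18 with empty histories slightly overweights
  low-history young adults relative to a real in-migration process.
- The model is a single closed city: no migration, no secular trends, no
  policy phase-in, perfect enforcement.
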