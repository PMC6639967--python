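# Methods

## The decision problem

Uncomplicated urinary tract infection (acute lower UTI in otherwise
healthy, non-pregnant women) can be assessed and treated at first contact
by a community pharmacist, a family physician, or an emergency physician.
The three pathways differ almost entirely in what the first (and, for
persistent infections, the second) contact costs the payer; cure rates and
health-state utilities are similar across prescribers.  The package
encodes this as a decision tree and asks the standard cost-utility
questions: what does each pathway cost in expectation, what health does it
return, which pathways sit on the cost-effectiveness frontier, and what
would expanding pharmacist access do to the payer's budget over five
years.

## Model structure

The tree has one branch per strategy.  A patient is cured by the initial
antibiotic course with her arm's cure probability (pharmacist 0.886, both
physician arms 0.90); otherwise her infection persists and she either
extends the initial antibiotic or switches to a fluoroquinolone, incurring
a follow-up contact and a second medication course.  All patients are
symptom-free by the end of the one-month horizon, nobody dies, and no
adverse events are modelled.  Costs are 2018 CAD and are not discounted
(horizon under a year).

Health outcome is the quality-adjusted life-month (QALM), computed as the
area under a piecewise-constant utility trajectory divided by the 30-day
horizon.  A cured patient spends the 14-day initial window at the
symptomatic baseline utility (0.68) and the remaining 16 days at the
cured-after-initial-treatment utility (0.83), giving 0.76 QALM.  A
persistent patient spends the last 16 days at the persisted utility
(0.76).

Three structural quantities are genuinely open and are exposed in
`StructureConfig` / `ParameterSet` rather than hard-coded:

- **Extend-vs-switch split** (`p_extend_vs_switch`, default 0.5): the share
  of persistent patients who extend the initial antibiotic rather than
  switch is not an observed quantity; 0.5 is an uninformative split.  It
  is a structural assumption, so the PSA holds it fixed.
- **Follow-up provider** (`followup_provider`): the persistent patient's
  second contact is a repeat pharmacist visit ($23.00) in the pharmacist
  arm and a family follow-up visit ($38.35) in both physician arms — a
  follow-up fee exists only for family care, and a second emergency visit
  for persistent uncomplicated UTI is neither typical nor the cheaper
  reading.  Fully configurable.
- **Utility placement after persistence** (`persisted_cured_days`,
  default 0): the cured-after-subsequent-treatment utility (0.82) carries
  zero days by default (the horizon ends at assumed resolution).  Setting
  `persisted_cured_days = k` values the last *k* days of the subsequent
  window at 0.82 instead of 0.76.

The calendar convention is 1 month = 30 days = 14 + 16; QALM denominators
use 30.

## Probabilistic sensitivity analysis

Every uncertain input — cure rates, utilities, unit costs — is assigned a
distribution centred on its point estimate: beta for probabilities and
utilities, gamma for costs.  The stated uncertainty of "±25% of the point
estimate" is interpreted as a **95% interval half-width**, so
sd = 0.25 × mean / 1.96.  The alternatives (a ±25% uniform range, or 25%
as a coefficient of variation) make the beta fit infeasible or the support
overflow for utilities near 0.83 and cure rates near 0.9, so the interval
reading is the one consistent with the stated distribution families.
Shape parameters come from the method of moments; a zero half-width
degenerates to the point mass.

Draws are independent across parameters and iterations (no correlation
structure is specified).  The family and emergency arms share a cure-rate
point estimate but are sampled independently by default; a
`shared_physician_cure_draw` toggle forces a common draw.  Each of the
10,000 default iterations rebuilds the tree from its drawn parameter set
and rolls it back; 95% intervals are the 2.5th/97.5th percentiles of the
draws, not a normal approximation.  The default seed 20180701 is
arbitrary and recorded in every output.

## Frontier and acceptability

`sequential_cea` is the textbook sequential algorithm: sort by ascending
cost, remove dominated strategies (weak dominance included — with equal
effects the costlier strategy is dominated), compute step ICERs between
adjacent survivors, and remove any strategy whose step ICER is not below
the next step's ICER (extended dominance), iterating until the ICER ladder
strictly increases.  Dominance analysis runs on PSA means, matching the
published presentation; a per-iteration frontier share is available as a
diagnostic.

Note one divergence from the published labels: at the published means, the
emergency-vs-family step ICER (≈5.67M $/QALM) *increases* along the
ladder, so the textbook rule keeps the emergency arm on the frontier,
whereas the source labels it extended-dominated.  The package implements
the textbook rule and does not attempt to reverse-engineer unrounded
inputs that would reproduce the label.

The CEAC evaluates, per willingness-to-pay value and iteration, the net
monetary benefit NMB = WTP × QALM − cost; the per-strategy probability is
the share of iterations it attains the maximum.  Exact NMB ties (a
measure-zero event except in degenerate analyses) are awarded to the
cheaper strategy — deterministic and conservative toward the cheaper
option.  The default WTP grid runs 0 to 5,000,000 $/QALM in 10,000-unit
steps, spanning the model's ICER magnitudes.

## Societal perspective

The societal scenario adds to each contact the value of work time lost
(hours × $22.97/h average wage: 4 h for a family visit, 8 h for an
emergency visit, 0 h for a pharmacy visit) and the patient's travel cost
($1.75/h parking for the contact's duration, or a $2.75-each-way transit
round trip).  Defaults: pharmacist and family arms travel by transit,
emergency by parking; the persistence follow-up contact repeats the
add-on of the arm that delivers it (`followup_addons`, default on — a
second contact plausibly repeats travel and time costs).  QALMs are
unchanged; only costs widen.

One limitation of the fee-key representation: the pharmacist arm's
follow-up visit bills the same `visit_cost[pharmacist]` key as its initial
visit, so turning `followup_addons` off still leaves the pharmacist
follow-up carrying the initial-visit add-on through the shared key.
Decoupling would need a separate follow-up fee key, which the fee schedule
does not define.

## Budget impact

The eligible population (women 25+ expected to seek care, 12% annual
incidence) starts at 1,614,384 in year 1 and grows 1% per year with
nearest-integer rounding after each year, reaching 1,679,934 in year 5.
The current scenario holds pharmacist uptake at 1%; the new scenario ramps
linearly to the target (25% / 50% / 75%) by year 5 — yearly uptake values
are not published, and a linear ramp is the simplest trajectory consistent
with "increase to the target over five years"; a config vector can
override it.  The non-pharmacist share splits between family and emergency
care; the default emergency share (0.040404) is calibrated so that the
year-1 current-scenario per-patient cost matches the published year-1
projection at the published mean per-patient costs, and is logged as a
calibration.  Yearly totals are rounded half-up to whole dollars; net
impact is new minus current, so negative values are savings.

`net_budget_impact` also accepts precomputed yearly totals, which is how
the published scenario series (whose new-scenario uptake trajectory is not
derivable from the stated ramp) are reduced to their net-impact
identities.

## What the synthetic data emulate

`generate_parameter_set` jitters every cost, probability and utility
multiplicatively (uniform, ±`jitter`), clipping probabilities to the open
unit interval — it produces plausible *parameter* sets, not plausible
*patients*.  `simulate_cohort` draws individual trajectories through the
tree as independent Bernoulli/categorical outcomes, which is exactly the
tree's own independence assumption; it therefore validates the roll-back
arithmetic, not the model's fidelity to real patients.  Real-world
features deliberately absent: antibiotic-specific effects, symptom-duration
heterogeneity, correlation between costs and outcomes, adverse events,
and progression to pyelonephritis.  Passing oracle tests shows the
computations are self-consistent, not that the model predicts real
cohorts.

Two independent seed-derived random streams (parameter jitter vs patient
outcomes) let tests vary one while holding the other.

## Numerical choices and problem sizes

- Chance-node probabilities must sum to 1 within 1e-12; trajectory
  durations must sum exactly to the horizon.
- Degenerate probabilities prune subtrees exactly (cure rate 1 leaves a
  single terminal), so zero-variance runs are bit-reproducible.
- Oracle tests compare microsimulation means to roll-back values within 3
  standard errors at n = 100,000 patients; distribution-moment checks use
  n = 10,000 draws within 4 standard errors; the frontier oracle sweeps
  200 random instances of up to 6 strategies against an exhaustive
  NMB-maximiser enumeration.  These sizes keep the full suite under a few
  seconds while leaving Monte Carlo tolerances comfortably bounded.

## Known limitations

The published per-strategy PSA mean costs and QALMs are not reproducible
from the published unit costs under any persistence structure this tree
can express (e.g. the pharmacist arm rolls back to ≈$41.97 against a
published mean of $72.47, and QALMs to ≈0.7557 against 0.75137); the cost
composition behind those means is under-specified at the source.  The
package documents the gap rather than tuning hidden costs to force
agreement: the reproducible surfaces are the ICER arithmetic, the
population projection and the budget-impact identities, plus the internal
oracles above.  Likewise the 50%/75% budget scenarios publish a different
current-scenario series than the 25% case although the current scenario
is uptake-independent; the package reproduces the 25% configuration and
treats the others as target-uptake variations of it.
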