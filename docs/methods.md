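# Methods

## Model structure

The model is a decision tree (choice of BHA, SB-THA or DM-THA for a
displaced femoral neck fracture) feeding identical annual-cycle Markov
models with the health states *well post-primary implant*, *well
post-R-THA*, *well post-RR-THA* and *dead*. A per-patient tracker counts
dislocations on the current implant: the first dislocation on an implant
is managed by reduction, the second requires revision, and the tracker
resets on revision. Because a second dislocation always revises, the
tracker saturates at 1 and the exact state space is finite:
(well-primary, post-R-THA) × (tracker 0, ≥1), plus post-RR-THA and dead —
six states. Death is absorbing and possible from every state.

Within a cycle, events resolve in a fixed order: death first (no accrual
in the cycle of death), then at most one mutually exclusive implant
event. Infection states and conservative/osteosynthesis arms are out of
scope.

## Event probabilities

SB-THA annual probabilities of dislocation, revision-for-dislocation and
revision-for-other-causes are tabulated for 5-year age bands 65–89; the
band is looked up from the patient's current (integer) age each cycle and
the last band extends upwards. DM-THA probabilities multiply the SB-THA
row by DM-vs-SB relative risks. No direct BHA-vs-SB ratios are published,
so BHA is chained through DM: dislocation divides the DM rate by the
DM-vs-BHA ratio; revisions multiply the DM rates by BHA-vs-DM ratios.
Derived probabilities are clamped to [0, 1] with a logged warning, and a
parameter set whose competing event probabilities sum above 1 in any
state is rejected at load time.

Two readings of the tabulated "revision dislocation" probability are
implemented (`rev_dis_all_states`): as a direct-to-revision event in
every well state, or only on the revised (DM) implant, with
primary-implant revisions arising from the non-dislocation probability
plus the tracker rule. The shipped default is the latter; with the former
the BHA arm accrues revision-dislocation events at 2.9× the SB table rate
(through the chained ratio 0.40 × 7.16), which depresses both pairwise
ICERs far below the published values.

## Costs and utilities

Cycle 1 replaces the annual maintenance cost with a surgery bundle:
initial-year care + implant + surgical fee for the chosen strategy. Every
later alive cycle accrues the annual well-maintenance cost. A reduction
adds the dislocation event cost; the cycle utility is the state utility
plus the one-cycle dislocation disutility. A revision (or re-revision)
cycle adds the R-THA fee, a DM implant, and — by default
(`revision_includes_initial_year`) — the initial-year THA care cost, on
the argument that a revision year entails the same hospitalisation and
rehabilitation as the index year; charging only fee + implant is the
config alternative. The inclusive default was selected because it
reproduces the published DM-vs-SB results (base ICER, the
dislocation-relative-risk threshold, the age at which DM-THA stops being
cost-effective, and the acceptability probabilities) far more closely,
whereas the exclusive variant misses all of them; see "Fidelity" below.

Post-revision state utilities are composites fixed at resolution time:
u(post-R-THA) = u(well post-DM-THA) + d(R-THA), likewise for RR-THA,
clamped to [0, 1]. The one-off disutilities are not additionally
subtracted in the event cycle (config switch
`event_cycle_extra_disutility` enables the additive alternative). Utility
of death is 0. All cycle utilities are clamped to [0, 1].

Costs and QALYs are discounted at 2%/year by 1/(1+r)^(t−1) — the first
cycle undiscounted; `discount_from_first_cycle` switches to
1/(1+r)^t. No half-cycle correction is applied.

## Evaluators

Two evaluators share the cycle semantics exactly:

- **Microsimulation** (first-order Monte Carlo): 100,000 independent
  patients per strategy by default, vectorised over trials, two uniform
  draws per patient-cycle. Streams are spawned per (strategy, stage) from
  one master seed (numpy Philox), so strategies are compared on
  independent randomness and every run is exactly reproducible. Reported
  Monte-Carlo standard errors are sample SD / √n.
- **Cohort expectation**: exact propagation of state-occupancy
  probabilities through the six-state space, with expected per-cycle
  accruals. It accepts vectorised parameter arrays, which makes the
  10,000-sample PSA a single broadcast pass.

The test suite enforces their statistical equivalence (microsimulation
means within 3 MC SE of the cohort value for every strategy and scenario
age). Sensitivity analyses, threshold searches, the PSA and the scenario
grids use the cohort evaluator by default: thresholds need a
deterministic objective, the published grid trends are monotone only net
of simulation noise, and the full nested design (100,000 trials inside
each of 10,000 PSA samples) buys no information here since the cohort
evaluator *is* the microsimulation's expectation. The nested mode remains
available (`evaluator="microsim"`).

## Sensitivity analyses

One-way analysis re-evaluates a pairwise ICER with one parameter at its
low/high bound; entries are sorted by ICER span (flagged entries —
dominated/dominant/undefined, the tornado's "infinity" cases, treated as
infinite span — sort first). Effect increments below 10⁻⁶ QALY are
"undefined". Threshold search brackets the sign change of ICER − WTP and
bisects to a relative tolerance of 10⁻⁶ on the parameter.

PSA distribution families by role: gamma (costs), log-normal (relative
risks), normal (disutilities), beta (utilities and probabilities).
Parameters are moment-matched to SE = (high − low)/(2 × 1.96); the
log-normal is centred so its *median* equals the point estimate, matching
the asymmetry of the published confidence intervals. Ranges known only by
a point estimate use SE = 0.2 × point. A beta whose moments are
infeasible falls back to a [0, 1]-truncated normal (logged). Draws are
independent across parameters (no published correlation structure); the
post-revision composite utilities are rebuilt per draw from their sampled
components. Infeasible joint draws (event sums above 1) are resampled and
counted. CEAC probabilities are argmax-NMB fractions over samples, ties
broken by lower cost then fixed strategy order; the default WTP grid is
0–20 M yen/QALY in 250,000-yen steps, covering the published curves.
Scatter summaries report per-sample (ΔE, ΔC), quadrant counts, and a 95%
confidence ellipse from the 2×2 sample covariance at the χ²(2 df) 0.95
quantile.

## Synthetic life tables

The official 2022 abridged Japanese life tables used by the published
analysis are supplementary material not reproducible from the article
text, so the package generates synthetic stand-ins from a Gompertz law
q(a) = 1 − exp(−b·e^{c(a−65)}), with (b, c) = (0.0024, 0.125) for women
and (0.0060, 0.105) for men — chosen once from public Japanese mortality
magnitudes (female q(75) ≈ 0.008, male ≈ 0.017, steeply increasing).
They emulate level and slope, not cohort effects, the abridged-interval
step structure, or the official table's exact values; absolute costs and
QALYs therefore carry a small life-table error (≲ 1% at the base case)
that largely cancels in increments. Abridged input tables are expanded
by repeating the interval value per single year of age; lookups floor
the age and extrapolate the last value upwards.

## Fidelity to the published results

With the shipped defaults and synthetic life tables, the model
reproduces (printed value; deviation): BHA QALY 3.792 (+0.1%), SB-THA
cost 8,669,497 (−0.4%), DM-vs-SB ICER 4,145,777 (−4%), acceptability at
5 M yen/QALY 40.1/38.5/21.4% (within ~2 points each), the SB
initial-year-cost threshold 2,983,027 (−3.9%), the DM-vs-SB tornado
thresholds for revision relative risk (0.958; −0.3%) and post-R-THA
utility (0.83; −4%), the horizon trends, and the female age at which
DM-THA crosses the threshold (between 75 and 80).

One family of quantities deviates systematically: our SB-vs-BHA QALY
increment is 0.207 against a printed 0.229, so the SB-vs-BHA ICER runs
≈ 10–18% high (base case 1.76 M vs 1.50 M; one-year horizon 6.45 M vs
5.81 M), and the dislocation-relative-risk threshold lands at 0.329 vs
0.348. The printed increment equals the bare utility difference
(0.05 × discounted survival) with almost no event drag, implying the
original implementation barely penalises post-revision quality of life
in that comparison — yet the DM-vs-SB increment (0.013) matches the
persistent composite-utility reading exactly. No single reading of the
published description satisfies both; the persistent reading is kept and
the discrepancy documented rather than patched per-comparison.

## Limitations

Beyond the published model's own scope (five-year horizon, no infection
state, all re-revisions assumed successful), this implementation assumes
the within-cycle event order stated above, no half-cycle correction, no
parameter correlation in the PSA, and synthetic mortality unless official
tables are supplied. Tests passing on synthetic tables demonstrate
internal correctness and reproduction of the published increments, not
calibration of absolute costs/QALYs to official Japanese mortality.
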