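# Methods

## The feeding-cycle model

One gonotrophic cycle is modelled as an absorbing process over discrete
blood-feeding attempts. The behaviour profile fixes baseline attempt
weights over five compartments (human indoor in-bed / indoor out-of-bed
/ outdoor, livestock, other animals); the weights are non-negative and
sum to one by construction. Per attempt, an attack on a resource covered
by an intervention (probability = that intervention's coverage) is
killed pre-bite, blocked non-lethally, or passes; several interventions
guarding one compartment are met sequentially in stack order, each
acting as an independent per-attempt hazard — independence is the
minimal assumption where interaction data do not exist. Blocked attempts
restart; killed and fed attempts absorb. Solving the geometric recursion
gives the closed forms quoted in the README. The model has no time step:
it is a per-cycle bookkeeping of fates, not population dynamics, so
seasonality, age structure and spatial movement are out of scope by
design.

Post-bite mortality is compounded as independent hazards conditional on
where the meal was taken: IRS reaches only the fraction of indoor feeds
that rest on sprayed surfaces (`r_indoor_rest * coverage * post_kill`),
endectocides only livestock feeds (`coverage * post_kill`), while sugar
baits (`sugar_rate * coverage * post_kill`) and swarm sprays
(`coverage * post_kill`) apply to all fed survivors once per cycle.

### Encounter multiplication and population coverage

Personal protection of a fraction `u` of a host class with per-encounter
block probability `b` reduces that class's relative blood availability
to `Z = 1 - u*b`, so a mosquito needs `E = 1/Z` encounters (house
entries) per meal. The default `b = 0.625` is a named calibration
constant chosen so that 80% net usage doubles `E`; it is overridable in
every API and config that accepts a block probability. Whether blocking
applies to all indoor encounters or only to hosts in bed is not
empirically separable at this level of description; the calibrated `b`
absorbs the distinction.

Population coverage of a house-delivered insecticide is the probability
of at least one indoor encounter with a covered house over `e`
independent entries, scaled by the human-fed fraction:
`C_M = q_human * (1 - (1 - pi_indoor * c_h)^e)`. At `e = 1` this reduces
to the simple product `q * pi * c_h`. Inside `CycleOutcome`, the
per-intervention `c_m` uses the attempt-level analogue
`1 - (1 - sum_j a_j * coverage)^E` over the intervention's target
compartments; the two coincide at `q = 1` and at `e = 1` and differ only
in how the human-fed fraction enters the exponentiation for mixed
feeders — the attempt-level form is the one consistent with the cycle
model's own attempt process.

### The layering trace and the transmission proxy

`apply_stack` recomputes the cycle on every cumulative prefix of the
stack; redistribution of residual meals is the instantaneous
renormalisation of the feeding probabilities (behavioural resilience).
Heritable shifts in innate preference (behavioural resistance) are
deliberately outside the model.

The relative transmission proxy is the expected number of lifetime human
feeds under geometric survival, normalised to baseline:
`T_k = [h_k / (1 - s*S_k)] / [h_0 / (1 - s*S_0)]`, with `h` the
probability of a human feed in the cycle, `S` the intervention-attributable
per-cycle survival and `s` the natural per-cycle survival from all other
causes (default 0.85, a typical value for African vectors; any value in
[0, 1) is accepted). The natural-mortality factor is essential: an
unperturbed cycle has `S_0 = 1`, so without `s < 1` the baseline
expectation diverges and layer-on-layer comparisons degenerate to 0/inf.
The proxy omits the sporogonic delay and the squared human-biting term of
a full vectorial-capacity calculation; it ranks stacks, it does not
predict EIR.

`remeasure` inverts the residual meal distribution back to the profile a
post-intervention survey would record. The indoor-resting and
sugar-feeding propensities are innate per-compartment traits that the
meal distribution cannot identify, so they carry over from the
pre-intervention profile attached to the outcome.

## Indicator estimators

Exposure weights are biting rate times person-time at risk per hour bin
(24 half-open bins): `w_in(t) = B_in(t)*H_in(t)`,
`w_out(t) = B_out(t)*(1 - H_in(t))`; `pi_indoor` is the indoor share of
their total and is invariant to rescaling all rates. The residual
outdoor fraction under screening of efficacy `s` is
`sum w_out / (sum w_out + (1-s) * sum w_in)`.

All proportions carry two-sided Wilson score intervals (via statsmodels),
chosen over Wald for honest behaviour at the 0/1 boundaries that small
entomological samples regularly hit. Mixed blood meals ("human+cattle")
count half toward each named host; the weight is configurable. The
indoor-resting fraction is the simple proportion of fed specimens from
paired indoor/outdoor resting collections, uncorrected for differential
collection efficiency between locations — the result's method tag flags
the approximation.

## Decision rules

Each technology row combines human-context flags with "at least
one-third" thresholds on the relevant behavioural fraction. The
comparison is `>= 1/3` against the double nearest 1/3 with no tolerance
band: one-third itself triggers ("at least"), anything strictly below
does not. Where historical and current indoor-exposure values are both
supplied, the maximum applies — a population that fed indoors before
control can be targeted indoors again. Sugar-bait and swarm-spray rows
have no accepted numeric threshold; they are boolean labelling-study
outcomes.

## Synthetic data

The generator emulates the survey instruments, not any particular field
dataset. Defaults, chosen once as field-realistic values:

| parameter | default | why |
|---|---|---|
| biting peaks | 21 h and 05 h, von Mises κ = 2, weights 0.6/0.4 | evening/morning bimodality typical of African vectors |
| schedule | indoors 20 h, bed 22 h, rise 05 h, leave 06 h | step-function time budget of a rural household |
| person_nights | 500 | a realistic multi-week catch effort per site |
| n_bloodmeals | 200 | a large resting-collection campaign |
| counting noise | Poisson | the minimal model for count data |
| site heterogeneity | Beta, concentration 2/spread (spread 0.8) | spans essentially (0.01, 0.99) at high spread |
| indoor-resting rate | log-normal, median 0.02, log-sd 1.2 | spans several-hundred-fold over 1000 sites |

The indoor/outdoor split of the biting rates is solved analytically so
that the exposure-weighted indoor proportion equals the configured truth
exactly in the noiseless limit; the in-bed exposure share then follows
from the schedule and the biting curve rather than being an independent
dial. All randomness flows through one seeded NumPy generator; a fixed
seed gives byte-identical tables.

What passing tests on these data do **not** show: robustness to trap
bias, to non-Poisson overdispersion from mosquito aggregation, to
misidentified blood meals, or to human schedules less regular than a
step function. Real surveys have all four.

## Numerical choices

Inputs outside [0, 1] by more than 1e-9 are rejected, never clamped.
Fate-probability conservation holds to 1e-12 (verified by sweep).
Per-attempt blocking mass within 1e-9 of 1 raises a total-blockade
error rather than returning a divergent expectation. JSON reports keep
full double precision; probability-like fields are validated against
[0, 1] before writing.

## Problem sizes

The stochastic cross-check replays 1e5 mosquitoes per scenario over
five randomised scenarios and compares every fate probability within
three binomial standard errors. Estimator studies use 200 replicate
surveys at 500 person-nights and 200 blood meals (500 replicates for
interval-coverage checks). The decision-rule truth table is exhaustive:
64 flag combinations x 64 indicator triples. These sizes make the full
suite and the acceptance script complete in well under a minute while
keeping Monte-Carlo error far below every asserted tolerance.

## Known limitations

- Coverage is a single scalar per intervention; within-house and
  within-herd heterogeneity of protection are not represented.
- Layered interventions compound independently; synergies or
  antagonisms (e.g. repellency reducing IRS contact) are not modelled.
- The transmission proxy ignores the extrinsic incubation period, so it
  understates the survival-sensitivity of transmission.
- Evolved (heritable) behavioural change is out of scope; the
  redistribution modelled here is instantaneous plasticity only.
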