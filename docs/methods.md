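# Methods

## Model structure and assumptions

The model is a closed-cohort (Markov) state-transition model with a 1-week
cycle and five states: first-line treatment, progression (transient, one
week), second-line treatment, progressed without treatment, and death
(absorbing). The population is metastatic colorectal cancer patients at the
moment hand-foot syndrome or cardiovascular toxicity forces a decision about
their fluoropyrimidine-based first-line treatment; week 0 is that moment,
and the fitted survival curves apply from this origin.

Overall survival (OS) and time-to-progression (TTP) are Weibull,
`S(t) = exp(-(t/scale)^shape)` with time in weeks. The weekly transition
probability out of an event-free week t is `1 − S(t+1)/S(t)`, recomputed
every week from the Weibull (no constant-rate approximation — the Weibull
was chosen over the exponential for fit, and an exponential would erase
exactly that time-dependence). Treatment effects multiply the weekly
*probability* (clamped at 1) rather than the hazard; at the weekly
probabilities involved (< 0.05 over the whole horizon) the two conventions
agree within 2% relative for the relative risks used, so the simpler
probability reading is honoured (a property test documents the bound).

Structural choices the problem leaves open, resolved here as model design:

* **Event order within a week.** Death is evaluated before progression and
  before the second-line split. This makes the cohort's survival curve
  reproduce the fitted OS curve exactly when the relative risk is 1 (an
  engine test asserts agreement to 1e-6 at every week).
* **One mortality process.** The same time-from-baseline OS process,
  adjusted by the strategy's relative risk, applies in every alive state; no
  separate post-progression survival model is introduced.
* **Strategy-wide relative risks.** A strategy's `rr_os`/`rr_ttp` apply for
  the whole trajectory (S-1 strategies: 0.93 on death, 1.0 on progression;
  discontinuation: 1.50 on both; reduced-dose continuation: 1.0, i.e.
  reduced dosing is assumed fully effective).
* **Second-line treatment continues until death** — no stopping rule is
  imposed; costs accrue for the entire occupancy of that state. All
  second-line options are assumed equally effective.
* **No half-cycle correction**: with weekly cycles the correction is far
  below every other source of error.
* **Horizon 780 weeks (~15 years)** operationalises "lifetime": the alive
  fraction at the horizon is below 0.1% for all strategies and parameter
  draws, verified by test.

## Parameters

All calibration values live in the bundled YAML configs
(`src/chemoswitch/configs/`), one per scenario. The key quantities, with
units and defaults:

| parameter | default | unit / note |
|---|---|---|
| OS Weibull (shape, scale) | 1.473, 79.4 | weeks |
| TTP Weibull (shape, scale) | 1.560, 53.9 | weeks |
| RR death, S-1 vs fluoropyrimidine | 0.93 | lognormal(−0.0726, 0.058) in PSA |
| RR death & progression, no treatment | 1.50 | fixed; 1.2/1.8 in sensitivity |
| second-line uptake | 0.80 | of progressing patients |
| utility first line | 0.83 | normal(0.83, 0.01), truncated to [0,1] |
| decrement second line / untreated | 0.15 / 0.10 | utility points |
| AE disutility, duration | 0.15, 2 weeks | see below |
| recurrent HFS prob. (fluoropyrimidine / S-1) | 0.55 / 0.05 | cost €50 |
| recurrent CVT prob. (fluoropyrimidine / S-1) | 0.40 / 0.04 | cost €200 |
| discount rates | 3% costs, 1.5% QALYs | per year, weeks_per_year = 52.18 |
| horizon | 780 | weeks |

Costs are stored per treatment cycle as *named components* (drug and
administration items) and divided by the cycle length (3 weeks for oral and
short-infusion regimens, 2 weeks for i.v.-5FU-based ones). The CAPOX weekly
cost is taken from its components, (180 + 556 + 335)/3 = €357/week, which is
consistent with every other regimen's arithmetic; irinotecan monotherapy is
assigned a 3-week cycle (350 mg/m² schedule), the only cycle length
consistent with €337/week. No inflation indexing or currency conversion is
performed.

Adverse events: only recurrent HFS and CVT carry costs; the expected cost
(e.g. 0.55·50 + 0.40·200 = €107.5 on the capecitabine-continuation arm) is
applied to the whole cohort once at week 0, undiscounted. Both
probabilities act on everyone simultaneously rather than on disjoint
subgroups — the only reading consistent with that expected-cost column.
Diarrhoea and anorexia default to probability 0 and would enter only
through disutility. Disutilities for co-occurring events are
probability-weighted and additive, floored at utility 0. The event duration
is a config knob (`ae.duration_weeks`); the default is 2 weeks, and moving
to 3 weeks changes QALYs by well under 0.01. The transient progression week
carries the progressed-untreated decrement (0.10).

## Uncertainty propagation

The PSA draws, per run: every named cost component from a gamma with shape
√c and rate 1/√c (mean exactly c, variance c^1.5); the S-1 OS relative risk
from its lognormal (applied to S-1 strategies only — the discontinuation
relative risk has no uncertainty distribution and stays fixed); the
first-line utility from a normal truncated to [0, 1] by resampling; and the
OS and TTP (shape, scale) pairs from correlated bivariate normals
(correlations 0.555 and −0.255), redrawn in the practically impossible
event of a non-positive value. One draw is shared by all strategies within
a run, so incremental quantities are paired. Each run owns a random stream
spawned from the master seed (`numpy.random.SeedSequence`), making results
independent of execution order and bit-reproducible. `sigma_scale` scales
all spreads and collapses the PSA onto the point estimates at 0, which is
how the means-converge-to-deterministic property is tested.

ICERs are computed on PSA-mean costs and QALYs, not as means of per-run
ratios. The frontier removes strictly dominated strategies, then
iteratively removes extended-dominated ones until stepwise ICERs increase
strictly. Strategies within 0.005 QALY and €100 of a frontier member are
reported as *equivalent* rather than dominated — differences that small are
below the model's resolution. Net-benefit ties break toward the cheaper
strategy (conservative payer perspective). The CEAC uses a WTP grid from 0
to €100 000 in €1000 steps. Both a frontier table and a
pairwise-versus-reference ICER column are emitted, since results are
commonly presented both ways.

Sensitivity analyses rerun the full PSA with the discontinuation relative
risk at 1.2 or 1.8, or with the OS Weibull parameters (means, SEs and their
correlation) replaced by a left-truncated refit on synthetic-trial patients
surviving 9 weeks — hand-foot syndrome typically emerges only after about
three full 3-week cycles.

## Synthetic trial emulation

The survival calibration was originally done on randomized-trial data that
are not deposited, so the package ships a generator instead of data. It
draws OS and TTP independently from their Weibulls, caps TTP at OS (death
before progression censors TTP at the death time), and applies
administrative censoring; the default emulation is phase-III-like, n = 160
with uniform accrual over 2 years and a data cutoff at 3 years, which
yields roughly 20–30% OS censoring. Parameter estimation is censored
maximum likelihood delegated to lifelines (`WeibullFitter` /
`ExponentialFitter`, with `entry` for the delayed-entry landmark refit);
tests check it against closed forms (uncensored exponential MLE = sample
mean) and generating-parameter recovery within 3 standard errors, including
Wald-interval coverage across replicate simulations.

What the generator does *not* emulate: dependence between TTP and OS beyond
the min-capping (no joint model is claimed), informative censoring,
treatment crossover, or the real trial's exact sample size and follow-up
(not public). Passing tests therefore show that the pipeline recovers known
generating processes and that the model reproduces the published results
under the published parameters — not that those parameters are correct for
any particular clinic. Quantities that depend on the real patient data —
the Kaplan–Meier medians, the bootstrapped shape–scale correlations, and
the published model-median-TTP column — are treated as inputs, not as
reproduction targets; the bootstrap machinery is validated for stability
and bounds only.

## Numerical choices

* Transition probabilities are computed in log-space (`exp(logS(t+1) −
  logS(t))`), robust to survival underflow at extreme parameters.
* Trace invariants — rows sum to 1 within 1e-9, death occupancy monotone,
  the transient progression state equal to its weekly inflow — are asserted
  across random parameter draws.
* Medians on the weekly grid are the first week at which the cumulative
  probability reaches the threshold; months = weeks × 7/30.44. The median
  TTP is reported two ways (among progressors, and marginal over the
  cohort) because no single definition is canonical when not all patients
  progress; neither is used for comparisons.
* Mean treatment cycles are undiscounted person-weeks in state divided by
  the cycle length; a discontinuation strategy reports 0 first-line cycles.
* Reported problem sizes: 1000 PSA runs per scenario (the analysis'
  specified size); trial-emulation tests use n between 160 and 5000
  depending on what the check needs (coverage at trial scale, recovery at
  large n).

## Known limitations

* The discontinuation relative risk (1.50, expert-based) is the model's
  most influential uncertain input, as the sensitivity analyses show; it is
  fixed in the PSA because no uncertainty distribution is available.
* Third-line treatment, bevacizumab (costs and effects assumed to cancel)
  and re-derivation of drug prices from dosing schedules are out of scope;
  per-cycle costs are inputs.
* The cohort engine tracks fractions, not individuals; questions needing
  patient-level heterogeneity (e.g. time-varying utilities per patient)
  would require a microsimulation.
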