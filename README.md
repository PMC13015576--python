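# chemoswitch

Cost-effectiveness modelling of switching to S-1-based chemotherapy after
fluoropyrimidine-induced hand-foot syndrome (HFS) or cardiovascular toxicity
(CVT) in metastatic colorectal cancer (mCRC).

The fluoropyrimidines capecitabine and intravenous 5-fluorouracil (5FU) are
the backbone of systemic mCRC treatment; HFS and CVT can force dose
reductions or discontinuation. S-1 is an oral fluoropyrimidine with a lower
incidence of both toxicities, licensed precisely for this switch. This
package models, for a payer choosing between *discontinuing*, *continuing at
reduced dose* or *switching to S-1-based treatment*, the lifetime costs and
quality-adjusted life years (QALYs) of each strategy, and asks which choices
are cost-effective at a given willingness to pay (WTP).

## The model

A closed cohort moves through five mutually exclusive health states in
1-week cycles:

```
first-line treatment ──► progression (1 week) ──► second-line treatment
        │                      │    └───────────► no further treatment
        └──────────────────────┴──────────────────────────┴──► death
```

* Overall survival (OS) and time-to-progression (TTP) follow Weibull
  distributions, `S(t) = exp(-(t/λ)^k)` with time in weeks:
  OS ~ Weibull(k = 1.473, λ = 79.4), TTP ~ Weibull(k = 1.560, λ = 53.9).
  Weekly transition probabilities are `p_t = 1 − S(t+1)/S(t)`, multiplied by
  a strategy-specific relative risk (RR): 0.93 on death for S-1, 1.50 on
  death and progression for discontinuation.
* 80% of progressing patients start second-line treatment after a one-week
  transient progression state.
* Costs (EUR, medication + i.v. administration per week of state occupancy,
  plus a one-off expected adverse-event cost) are discounted at 3%/year;
  QALYs (utility 0.83 first line, −0.15 on second line, −0.10 untreated
  after progression, adverse-event disutility 0.15 for 2 weeks) at 1.5%/year.
* A probabilistic sensitivity analysis (PSA, 1000 runs) propagates parameter
  uncertainty: gamma-distributed costs (shape √c, rate 1/√c), a lognormal
  S-1 relative risk, a truncated-normal utility, and correlated bivariate
  normal Weibull (shape, scale) pairs.
* Strategies are compared by incremental cost-effectiveness ratios (ICER =
  ΔCost/ΔQALY) on PSA means, a dominance/extended-dominance frontier, and
  net monetary benefit `NMB = WTP × QALYs − Cost` summarised as
  cost-effectiveness acceptability curves (CEAC).

Because the calibration trial's patient-level data are not public, a
synthetic-trial module (`chemoswitch.trial`) simulates right-censored OS/TTP
data at trial scale, fits exponential and Weibull models by censored maximum
likelihood (via lifelines), compares AIC, bootstraps the shape–scale
correlation, and supports the left-truncated 9-week landmark refit used in
sensitivity analysis.

## Worked example

Three scenarios are bundled, one per first-line regimen on which the
toxicity occurred: `capox`, `folfox`, `cap_mono`. Run scenario 1 (toxicity
on CAPOX, four strategies):

```bash
chemoswitch run capox --runs 1000 --seed 1 --out capox_out
```

prints

```
scenario 'capox': 4 strategies, OS Weibull(1.473, 79.4), TTP Weibull(1.56, 53.9)
CEAC turning point: 62000 EUR/QALY
                strategy  mean_cost  mean_qalys             status  icer_vs_previous  icer_vs_reference
         stop_irinotecan   6,915.24        0.80          reference               NaN                NaN
reduced_capox_irinotecan  22,176.94        1.04 extended_dominated               NaN          63,061.70
          sox_irinotecan  24,878.68        1.09        on_frontier         61,073.17          61,073.17
                sox_iris  24,928.10        1.09         equivalent               NaN          61,241.18
```

Reading this: discontinuation until progression is cheapest but yields the
fewest QALYs. Continuing reduced-dose CAPOX is *extended-dominated* — the
pricier switch to SOX (S-1 + oxaliplatin) buys QALYs at a lower incremental
price — so the decision-relevant ICER is SOX versus discontinuation,
≈ €61 000 per QALY. That sits below the €80 000/QALY threshold used for
high-burden conditions in the Netherlands, and the acceptability curves
cross (discontinuation stops being the most probable winner) near a WTP of
€62 000/QALY. The two SOX strategies (second-line irinotecan versus IRIS)
are equivalent within the model's resolution; the equivalent strategy keeps
its pairwise ICER versus the reference in the last column.

The output directory contains the per-strategy cohort traces, the per-run
PSA table, the frontier and CEAC tables, the exact parameter snapshot used
(`config_used.yaml`) and a manifest; rerunning with the same seed reproduces
every numeric file byte for byte.

Other entry points: `chemoswitch sensitivity capox --variant rr18` (vary the
discontinuation relative risk, or `cond9w` for the 9-week-survivor OS
refit), `chemoswitch simulate` (synthetic trial data + fit summary),
`chemoswitch ceac-plot`. The same functionality is available as a library:

```python
from chemoswitch import load_scenario, run_psa, frontier, ceac

bundle = load_scenario("capox")
psa = run_psa(bundle, n_runs=1000, seed=1)
print(frontier(psa.means(), reference="stop_irinotecan").table)
```

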