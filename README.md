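# hipcea

Cost-effectiveness analysis of the three prosthetic options for displaced
femoral neck fractures in active older patients — bipolar hemiarthroplasty
(BHA), single-bearing total hip arthroplasty (SB-THA), and dual-mobility THA
(DM-THA) — from the Japanese public healthcare payer's perspective.

The package is aimed at health-economics researchers and orthopaedic
decision-makers who want a reproducible, scriptable implementation of this
decision model: a decision tree feeding an annual-cycle Markov model with a
dislocation **tracker** variable, evaluated by first-order Monte Carlo
microsimulation and by an exact cohort-expectation engine, with one-way and
probabilistic sensitivity analyses and age/sex/horizon scenario grids.

## The model

A patient (base case: a 75-year-old woman) receives one of the three
implants and then occupies one of four health states: *well after the
primary implant*, *well after revision THA* (R-THA), *well after
re-revision THA* (RR-THA), or *dead*. Each annual cycle, for horizon
T = 5 years:

1. death occurs with the age- and sex-specific life-table probability
   q(age); death is absorbing and cancels the cycle's accrual;
2. otherwise at most one implant event occurs: a **revision** for causes
   other than dislocation, or a **dislocation** — managed by closed/open
   reduction the first time on a given implant (tracker 0 → 1) and by
   revision the second time. Every revision implants a dual-mobility cup,
   so post-revision risks are DM-THA risks; re-revised patients have no
   further implant events.

Annual SB-THA event probabilities are tabulated by 5-year age band;
DM-THA and BHA probabilities are derived through published relative
risks (BHA chained through DM, the only published reference). Costs
(2022 yen) and utilities accrue per cycle and are discounted at 2%/year:

- QALYs: state utility × 1 year (well post-BHA 0.820, well post-THA
  0.870, post-R-THA 0.870 − 0.185 = 0.685, post-RR-THA 0.583, dead 0),
- costs: a first-cycle surgery bundle (initial-year care + implant +
  surgical fee), an annual maintenance cost thereafter, plus event costs.

Decision outputs are incremental cost-effectiveness ratios
ICER = ΔC/ΔE along the cost-sorted frontier (with strict and extended
dominance), compared with the Japanese willingness-to-pay threshold of
5,000,000 yen/QALY; net monetary benefit NMB = λ·E − C drives the
acceptability curves. The probabilistic sensitivity analysis samples
costs from gamma, relative risks from log-normal (median-centred),
disutilities from normal, and utilities/probabilities from beta
distributions, all moment-matched to the published point ± range.

## Worked example

The published supplementary life tables are not redistributable, so the
package ships a synthetic Gompertz life table calibrated to Japanese
old-age mortality magnitudes; users with the official tables can pass
them with `--life-table` (CSV with `age,qx` columns).

```sh
hipcea basecase --evaluator cohort --out results/
```

prints the three-strategy table (deterministic cohort expectation):

```
Intervention    Cost Incremental cost QALYs Incremental QALYs    ICER      Status
         BHA 8268014               NA 3.795                NA      NA   reference
      SB-THA 8633954           365940 4.003             0.207 1764986 on-frontier
      DM-THA 8685783            51829 4.016             0.013 3978725 on-frontier
```

Reading: over five years a 75-year-old woman accrues about 8.27 M yen
and 3.80 QALYs under BHA. SB-THA buys 0.207 extra QALYs for 365,940 yen
more (ICER ≈ 1.76 M yen/QALY) and DM-THA a further 0.013 QALYs
(ICER ≈ 3.98 M yen/QALY) — both below the 5 M yen/QALY threshold, so
both are cost-effective for this patient. Other stages:

```sh
hipcea ceac --n-samples 10000 --out results/       # acceptability curves
hipcea tornado --target DM-THA --comparator SB-THA --out results/
hipcea threshold --target DM-THA --comparator SB-THA \
       --parameter rr_dis_dm_vs_sb --out results/
hipcea scenarios --axes age,sex --out results/     # Scenario A grid
hipcea scenarios --axes horizon --out results/     # Scenario B sweep
hipcea synth-lifetable --sex male --out male.csv
```

Every run writes delimited tables plus a `manifest.json` (seed, config,
parameter checksum) sufficient to reproduce it bit-for-bit. The same
functionality is available as a library (`hipcea.run_microsimulation`,
`hipcea.cohort_expectation`, `hipcea.run_psa`, `hipcea.tornado`, ...).

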