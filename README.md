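# iudcea

Cost-effectiveness analysis of expanding intrauterine-device (IUD) provision
by trained nurses in Brazil's Unified Health System (SUS), built as an open,
tested Python pipeline.

The package is aimed at health-economics analysts and reproductive-health
researchers who want a transparent, scriptable alternative to spreadsheet or
point-and-click decision-tree tools for this class of problem: a short-horizon
Markov cohort model of contraceptive uptake, a cost-effectiveness ranking with
dominance rules, and full deterministic and probabilistic sensitivity
analysis.

## The model

A cohort of women of reproductive age who wish to avoid pregnancy is
distributed over four mutually exclusive health states,

> not pregnant without IUD -> not pregnant with IUD -> pregnant with IUD,
> and pregnant without IUD,

and updated monthly by a row-stochastic transition matrix **P** built from:
the per-cycle provision probability *p* (how fast eligible non-users receive
an IUD under a scenario), pregnancy probabilities without/with the device,
and a pregnancy-loss probability returning the cohort to a non-pregnant
state. Within a cycle, uptake is evaluated before pregnancy risk.

Each scenario accumulates, per cycle *t* over a 3-month horizon with no
discounting:

- **QALYs** = sum over cycles of occupancy-weighted state utilities x 1/12
  (utilities: 1 with IUD, 0.8 without, disutility -0.1 for pregnancy on the
  method);
- **costs** (2023 BRL) = insertion (BRL 91.02) on entry into the with-IUD
  state, consultation per cycle without the device, an unintended-pregnancy
  cost on entry into a pregnant state, plus nurse training (BRL 1,820.38 per
  professional) once per scenario.

Strategies are then ranked by ascending cost; strongly and extendedly
dominated options are labelled; the incremental cost-effectiveness ratio
ICER = deltaC/deltaE and net monetary benefit NMB = E x lambda - C are reported at a
willingness-to-pay lambda = BRL 40,000/QALY (flexible to 120,000). Uncertainty
is handled by one-way tornado analysis and a 10,000-iteration Monte Carlo
PSA (beta distributions for probabilities/utilities, gamma for costs),
summarised as cost-effectiveness acceptability curves and incremental
cost-effectiveness scatters with 95% confidence ellipses.

## Worked example

Rank the four published provision scenarios (costs in BRL, effectiveness in
QALYs) at lambda = 40,000:

```python
from iudcea import StrategyResult, build_cea_table

table = build_cea_table(
    [StrategyResult("Pernambuco", 3813, 4.3), StrategyResult("Scenario 1", 19655, 4.5),
     StrategyResult("Scenario 2", 48003, 4.0), StrategyResult("Scenario 3", 73819, 3.7)],
    wtp=40_000,
)
print(table.to_dataframe().to_string(index=False))
```

```
  strategy     dominance  cost  incremental_cost  effectiveness  incremental_effectiveness     icer      nmb
Pernambuco NOT_DOMINATED  3813               NaN            4.3                        NaN      NaN 168187.0
Scenario 1 NOT_DOMINATED 19655           15842.0            4.5                        0.2  79210.0 160345.0
Scenario 2     DOMINATED 48003           28348.0            4.0                       -0.5 -56696.0 111997.0
Scenario 3     DOMINATED 73819           54164.0            3.7                       -0.8 -67705.0  74181.0
```

Scenarios 2 and 3 cost more yet deliver fewer QALYs than Scenario 1, so they
are dominated (their negative ICERs are reported but flagged not
interpretable); expanding provision from the current level to Scenario 1
costs BRL 15,842 more and gains 0.2 QALYs. Incremental columns compare each
row with the nearest non-dominated row above it.

Run the cohort model itself from the built-in base-case fixture:

```python
from iudcea import paper_fixture, run_scenario, percent_increase

ps = paper_fixture()
tr = run_scenario(ps, "Scenario 1")
print(f"cost_total={tr.cost_total:.2f} BRL, qaly_total={tr.qaly_total:.4f}")
# cost_total=824406.60 BRL, qaly_total=145.0075
print(f"{percent_increase(0.0024, 0.032):.1f}%")   # 1233.3%
```

Several fixture inputs (monthly pregnancy probabilities, consultation and
pregnancy unit costs, the utility of pregnancy without an IUD) are not
published figures; they ship as clearly flagged assumptions (`assumed` paths
in the fixture) and should be replaced with local values for policy use.

## Command line

```bash
cea fixture --out config.yaml          # write the base-case configuration
cea validate --config config.yaml     # schema + invariant checks, all errors listed
cea run --config config.yaml --mode all --seed 7 --iterations 10000 --out results/
```

`--mode base` writes per-scenario trace CSVs and the ranked CEA table;
`dsa` a tornado CSV; `psa` the Monte Carlo draws, CEAC and ICE-scatter CSVs;
every run writes a JSON manifest recording seed, iteration count and stage
status. Reruns with the same configuration and seed are byte-identical.

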