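# hepacea

Markov cohort cost-utility analysis of **proton beam therapy (PBT) versus
stereotactic body radiotherapy (SBRT)** for inoperable advanced
hepatocellular carcinoma, from the perspective of a single-payer health
system (costs in NT$).

The package is aimed at health-economics analysts who want a tested,
scriptable state-transition model rather than a point-and-click decision
tree: every stage — parameter derivation, cohort trace, incremental
cost-effectiveness statistics, one-way and probabilistic sensitivity
analysis — is an importable function with a thin CLI on top.

## The model

A 3-state Markov cohort model (stable disease → progressive disease →
dead, death absorbing, no backward transitions) with monthly cycles over a
5-year (60-cycle) horizon. Everyone starts stable. Monthly transition
probabilities come from median times-to-event via

    P(1 month) = 1 − 0.5^(1/median)

State membership per cycle is credited with a life-table half-cycle
correction; utilities are annual QALY weights accrued at *u*/12 per month.
Outcomes:

- **ICER** = ΔC/ΔE — extra cost per QALY gained by PBT over SBRT, with
  dominance classification for the non-trade-off quadrants;
- **NMB(λ)** = ΔE·λ − ΔC over a willingness-to-pay grid from 0 to the
  national threshold λ = 3 × per-capita GDP = NT$2,157,024/QALY;
- **tornado** one-way analysis over every parameter's ±30% range, ranked
  by outcome spread;
- **PSA**: 10,000-sample Monte-Carlo with beta distributions for
  probabilities/utilities and log-normal for costs (moment-matched to the
  base value and ±30% range read as a central 95% interval), summarised as
  a cost-effectiveness acceptability curve (CEAC).

A synthetic-data module generates pseudo individual-level trial data
(exponential event times, Bernoulli grade ≥3 toxicity, perturbed costs,
microsimulated patient paths) so the whole pipeline is testable
end-to-end without external data.

## Worked example

```sh
python examples/base_case.py
```

prints (shipped base-case parameters):

```
   sbrt: modeled median survival 10.42 months (10 mo), cost NT$   2,022,090, effect 0.4255 QALYs
 proton: modeled median survival 18.25 months (18 mo), cost NT$   2,359,917, effect 0.6478 QALYs

incremental cost  dC = NT$337,827
incremental QALYs dE = 0.2224
ICER = NT$1,519,164 per QALY gained (trade-off)
incremental NMB at WTP NT$2,157,024/QALY = NT$141,845
```

PBT costs more and yields more QALYs (a trade-off); its ICER sits below
the willingness-to-pay threshold, so the incremental NMB is positive and
PBT is cost-effective at the national threshold. The other examples cover
the tornado ranking (`examples/tornado.py`), the PSA and CEAC
(`examples/psa.py`) and the microsimulation validation of the cohort
engine (`examples/synthetic_validation.py`). The same analyses are
available as CLI subcommands:

```sh
hepacea base-case --out results/
hepacea tornado   --out results/
hepacea psa       --out results/ --n 10000 --seed 1
hepacea audit-fixture --out results/
```

`audit-fixture` writes a CSV comparing every printed input cell with its
recomputed value (component sums, the 3% discount link, the ±30% bounds)
and flags the handful of internally inconsistent published cells, which
are kept verbatim. See `docs/methods.md` for conventions, assumptions and
known limitations.

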