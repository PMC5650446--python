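# Methods

## Model structure

A cohort of patients with inoperable advanced hepatocellular carcinoma is
followed through three health states — stable disease, progressive
disease, dead — in discrete monthly cycles over a 60-month horizon. The
transition structure is strictly forward (stable→progressive,
stable→dead, progressive→dead, plus self-loops); death is absorbing.
Background non-cancer mortality is excluded, so survival reflects
disease-specific mortality only. The whole cohort starts in the stable
state. The cycle-*t* occupancy equals the start vector left-multiplied by
the *t*-th power of the monthly transition matrix; the engine iterates
the multiplication and the tests verify the matrix-power identity and a
100,000-path microsimulation oracle.

Monthly transition probabilities derive from median times-to-event by
`p = 1 − 0.5^(1/m)`: the constant per-cycle probability under which half
the cohort has had the event after `m` cycles (geometric waiting time,
the discrete counterpart of an exponential with median `m`). The shipped
parameter file also stores the published probabilities directly; the
17-month SBRT median reproduces the published 0.0399/month at its printed
four-decimal precision, while the 31-month proton median gives 0.0221
against a published 0.0219 — the published cell is kept, the difference
is surfaced by the audit rather than silently patched.

## Parameters (shipped base case)

| parameter | proton | SBRT | units / notes |
|---|---|---|---|
| stable→progressive | 0.1295 | 0.109 | per month |
| stable→dead | 0.06697 | 0.08299 | per month |
| progressive→dead | 0.0219 | 0.0399 | per month |
| utility, stable | 0.399 | 0.375 | annual QALY weight |
| utility, progressive | 0.28 | 0.263 | annual QALY weight |
| cost, stable stage | 291,000 | 219,843 | NT$, discounted package |
| cost, progressive stage | 97,478 | 141,916 | NT$/month, discounted |
| grade ≥3 toxicity | 0.30 | 0.343 | incidence (cost already inside the progressive-stage subtotal) |

Willingness-to-pay: 3 × per-capita GDP = 3 × NT$719,008 =
NT$2,157,024/QALY. Sensitivity ranges are ±30% of base; the shipped file
stores the published bounds verbatim (authoritative for reproduction),
and `audit_fixture` flags the cells that are not base×(1∓0.30) at printed
precision — notably the proton progressive-state utility upper bound
(0.476 instead of 0.364) and the SBRT progressive-stage subtotal
(146,305 printed vs 145,855 from its components). New analyses should
prefer `build_sensitivity_range` over the anomalous printed cells.

## Conventions and numerical choices

- **Discounting.** The published discounted cost estimates equal the
  undiscounted billing subtotals × 0.97 (a single 3% reduction), so the
  default `paper_one_time` mode reproduces them exactly; standard
  per-cycle exponential discounting `(1+r)^(−t/12)` is selectable
  (`DiscountSpec(mode="per_cycle")`) and is then applied to both costs
  and QALYs inside the accrual.
- **Cost timing.** Default `package`: the stable-stage cost is charged
  once at model entry (a radiotherapy treatment package) and the
  progressive-stage cost per month of occupancy, matching how the two
  figures are labelled. `per_cycle` (both monthly) and `one_time` (both
  on state entry) are selectable; the reproducible desk-scale quantities
  do not depend on this choice.
- **Half-cycle correction.** Boundary averaging: cycle-*t* membership is
  the mean of the occupancies at cycles *t−1* and *t*. It changes
  life-years by at most half a cycle relative to the uncorrected sum
  (property-tested).
- **Utilities and toxicity.** Utilities are treated as already
  toxicity-adjusted (the published values were "reduced according to the
  incidence rate" upstream, with no stated formula). An optional
  multiplicative adjustment `u′ = u·(1 − incidence·w)` is available via
  `accrue(..., tox_utility_weight=w)` and is off (w = 0) by default.
- **Median survival.** Linear interpolation between the cycle boundaries
  bracketing the 50% survival crossing; the interpolated value is
  primary and nearest-month rounding is used only for comparison with
  integer-month summaries. A never-crossing curve raises
  `MedianNotReachedError`.
- **ICER and dominance.** ICER = ΔC/ΔE, computed only when ΔE ≠ 0;
  dominance labels (dominant / dominated / trade-off) partition the
  (ΔC, ΔE) plane exhaustively, and dominant/dominated comparisons should
  be reported by label rather than by a sign-ambiguous ratio.
- **Distribution fitting.** The ±30% range is read as a central 95%
  interval: sd = (high − low)/(2·1.96), mean = base; beta parameters by
  method of moments, log-normal by moment matching on the same mean/sd.
  A `uniform` rule (sample uniformly on [low, high]) is selectable. The
  published parameter table labels the cost rows "Constant" while the
  methods text assigns log-normal distributions to all costs; the
  fixture follows the text, since constant costs would empty the PSA and
  the cost rows of the one-way ranking.
- **PSA sampling.** One master seed; each parameter gets a deterministic
  substream (spawned in sorted-id order), so runs are bit-reproducible
  given (n, seed) and adding a parameter does not perturb the others'
  draws. Parameters are sampled independently (no published correlation
  structure); the two stable-state exit probabilities are re-drawn
  jointly whenever their sum exceeds 1, with the rejection count reported
  and a warning above a 1% rejection rate.
- **Tornado.** Default outcome is the incremental NMB at the WTP
  threshold (defined for every input); ICER is selectable. Entries are
  sorted by descending spread, with ties broken by parameter id so the
  report is permutation-invariant; risk shares are squared spreads
  normalised over the included entries.

## Synthetic data

`hepacea.synthetic` emulates the *structure* the analysis assumes:
exponential times-to-event with specified medians, Bernoulli grade ≥3
toxicity, log-normally perturbed costs, and patient paths stepped through
the same categorical monthly chain as the cohort trace (a single draw
over stay/progress/die per cycle, deliberately matching the cohort chain
exactly so the microsimulation oracle is exact in expectation). It does
not emulate covariate-dependent hazards, informative censoring,
patient-level cost billing, or the between-trial case-mix differences of
the source phase-II cohorts — so passing tests validate the model
arithmetic and its statistical conventions, not the clinical
transportability of the inputs.

Problem sizes used in the validation suite: 100,000 patients for
microsimulation and distribution-recovery checks (agreement asserted at a
familywise 3-standard-error level with a Bonferroni-corrected per-cell
bound), 2,000-sample PSA in the quick example with the 10,000-sample run
available via the CLI.

## Known limitations

- The published headline outputs (ΔE = 2.61 QALYs, ΔC = NT$557,907,
  ICER = NT$213,354, PSA 97%/4%, proton modeled median 16 months) are not
  recoverable from the published inputs under any cycle convention tried
  here: the printed ICER disagrees with its own ΔC/ΔE quotient by ≈0.2%,
  the two PSA probabilities do not sum to 100%, and the proton transition
  probabilities yield a modeled median of ≈18.3 months. This package
  reproduces the quantities that follow exactly from the inputs (WTP
  threshold, table sums, the discount link, range construction, the
  transition-probability formula, the 10-month SBRT median) and validates
  everything else by algebraic identities and Monte-Carlo oracles.
- Under the default conventions the one-way ranking is led by the
  progressive-stage costs and the proton progressive-state utility rather
  than by the utilities alone as in the published ranking; the ranking
  depends on the (unstated) outcome metric and cost-timing convention.
- Two strategies only; no efficiency frontier, EVPI, parameter
  correlation, time-varying transitions or tunnel states.
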