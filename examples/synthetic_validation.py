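"""Validate the cohort engine against microsimulated patient-level data.

Generates pseudo individual-level data with the structure the model
assumes — exponential survival times with a 17-month median, Bernoulli
grade >=3 toxicity at 34.3%, and 100,000 patient paths through the monthly
3-state chain — and checks that the analytic cohort trace and the
published transition-probability formula recover the same quantities.
"""

import numpy as np

from hepacea import (
    SyntheticTrialSpec,
    build_transition_matrix,
    load_paper_fixture,
    median_survival,
    monthly_prob_from_median,
    run_cohort,
    simulate_event_times,
    simulate_patient_paths,
    simulate_toxicity,
)

spec = SyntheticTrialSpec(n_patients=100_000, median_ttp=6.0, median_os=17.0, seed=0)
times = simulate_event_times(spec)
sample_median = float(np.median(times["ttd"]))
print(f"specified median OS 17.0 mo -> sample median {sample_median:.2f} mo")
print(f"implied monthly death probability {monthly_prob_from_median(sample_median):.5f}"
      f" (formula at 17 mo: {monthly_prob_from_median(17):.5f})")

tox = simulate_toxicity(100_000, 0.343, seed=1)
print(f"specified toxicity incidence 0.343 -> sample incidence {tox.mean():.4f}")

fixture = load_paper_fixture()
sbrt = fixture.strategies["sbrt"]
paths = simulate_patient_paths(sbrt, n=100_000, horizon=60, seed=2)
trace = run_cohort(build_transition_matrix(sbrt), horizon=60)
gap = np.abs(paths.occupancy() - trace.occupancy).max()
print(f"\nmicrosimulation vs cohort trace (SBRT, n=100,000):")
print(f"  largest occupancy discrepancy over 60 cycles: {gap:.5f}")
print(f"  modeled median survival: {median_survival(trace):.2f} mo "
      f"(empirical cycle-10 survival {1 - paths.occupancy()[10, 2]:.4f},"
      f" analytic {trace.survival[10]:.4f})")
print("\nAgreement at Monte-Carlo error confirms the trace arithmetic and the")
print("patient-level interpretation of the transition probabilities coincide.")
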