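# Base-case parameter fixture: published model inputs for the proton-beam
# versus SBRT cost-utility comparison in inoperable advanced HCC.
# Costs are NT$; "costs" below are the 3%-discounted base estimates, while
# cost_components carry the undiscounted billing breakdown used by the audit.
settings:
  horizon_cycles: 60
  annual_discount_rate: 0.03
  discount_mode: paper_one_time
  sensitivity_fraction: 0.30
  wtp:
    gdp_per_capita: 719008
    multiplier: 3

strategies:
  proton:
    transitions:
      stable_to_progressive: 0.1295
      stable_to_dead: 0.06697
      progressive_to_dead: 0.0219
    utilities:
      stable: 0.399
      progressive: 0.28
    costs:
      stable: 291000
      progressive: 97478
    toxicity:
      incidence: 0.30
      cost: 6493
    cost_components:
      treatment: 300000
      stable_lab: 0
      prog_lab: 94000
      prog_tox: 6493
      printed_subtotal_stable: 300000
      printed_subtotal_prog: 100493
      printed_total: 400493
  sbrt:
    transitions:
      stable_to_progressive: 0.109
      stable_to_dead: 0.08299
      progressive_to_dead: 0.0399
    utilities:
      stable: 0.375
      progressive: 0.263
    costs:
      stable: 219843
      progressive: 141916
    toxicity:
      incidence: 0.343
      cost: 63054
    cost_components:
      treatment: 213660
      stable_lab: 12982
      prog_lab: 82801
      prog_tox: 63054
      printed_subtotal_stable: 226642
      printed_subtotal_prog: 146305
      printed_total: 372947

# Printed +/-30% sensitivity ranges.  Printed cells are authoritative for
# reproduction; the audit recomputes base*(1-/+0.30) and flags mismatches
# (notably the proton progressive-state utility upper limit, 0.476).
ranges:
  proton.p_stable_to_prog: {base: 0.1295, low: 0.09, high: 0.1685, family: beta}
  proton.p_stable_to_dead: {base: 0.06697, low: 0.047, high: 0.08697, family: beta}
  proton.p_prog_to_dead: {base: 0.0219, low: 0.015, high: 0.029, family: beta}
  sbrt.p_stable_to_prog: {base: 0.109, low: 0.076, high: 0.142, family: beta}
  sbrt.p_stable_to_dead: {base: 0.08299, low: 0.0581, high: 0.1079, family: beta}
  sbrt.p_prog_to_dead: {base: 0.0399, low: 0.0279, high: 0.0519, family: beta}
  proton.u_stable: {base: 0.399, low: 0.279, high: 0.519, family: beta}
  proton.u_prog: {base: 0.28, low: 0.196, high: 0.476, family: beta}
  sbrt.u_stable: {base: 0.375, low: 0.263, high: 0.488, family: beta}
  sbrt.u_prog: {base: 0.263, low: 0.184, high: 0.342, family: beta}
  proton.c_stable: {base: 291000, low: 203700, high: 378300, family: lognormal}
  sbrt.c_stable: {base: 219843, low: 153890, high: 285796, family: lognormal}
  proton.c_prog: {base: 97478, low: 68235, high: 126721, family: lognormal}
  sbrt.c_prog: {base: 141916, low: 99341, high: 184491, family: lognormal}
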