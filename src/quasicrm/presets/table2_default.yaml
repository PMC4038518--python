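# Benchmark design configuration: three-skeleton robust design, target ET
# score derived from the elicited MTD toxicity profile, maximum 20 patients
# in cohorts of one starting at the lowest dose.
weights: [0.0, 0.5, 1.0, 1.5]
s_max: 1.5
target_profile: [0.49, 0.18, 0.23, 0.10]
skeletons:
  - [0.11, 0.25, 0.40, 0.55, 0.70, 0.85]
  - [0.01, 0.03, 0.07, 0.12, 0.16, 0.20]
  - [0.20, 0.35, 0.50, 0.65, 0.80, 0.95]
prior_weights: uniform
prior_var: 2.0
max_n: 20
cohort_size: 1
start_dose: 1
# The published benchmark shows no early-stop mass (selection rows sum to 1,
# patient rows to 20, even under the most toxic truth), so the reproduction
# preset disables the safety rule; lower to e.g. 0.90 for a real trial design.
stop_cutoff: 1.0
quad_order: 12
escalation_restricted: true
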