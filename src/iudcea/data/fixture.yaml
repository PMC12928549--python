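scenarios:
- name: Pernambuco
  p_provision: 0.0024
  cohort_size: 600
  n_professionals: 1
- name: Scenario 1
  p_provision: 0.02
  cohort_size: 734
  n_professionals: 1
- name: Scenario 2
  p_provision: 0.032
  cohort_size: 1226
  n_professionals: 1
- name: Scenario 3
  p_provision: 0.04
  cohort_size: 1532
  n_professionals: 1
transitions:
  p_preg_no_iud: 0.14622990588362894
  p_preg_iud: 0.0006691236782786492
  p_loss: 0.0
  p_provision: 0.0
  retain_iud_after_loss: false
utilities:
  u_iud_no_preg: 1.0
  u_no_iud_no_preg: 0.8
  disutility_preg_iud: -0.1
  u_preg_no_iud: 0.7
costs:
  c_training_per_professional: 1820.38
  c_insertion: 91.02
  c_consultation_no_iud: 10.0
  c_unintended_pregnancy: 3000.0
config:
  n_cycles: 3
  cycle_length: 0.08333333333333333
  discount_rate: 0.0
  half_cycle_correction: false
  wtp_primary: 40000.0
  wtp_max: 120000.0
assumed:
- transitions.p_preg_no_iud
- transitions.p_preg_iud
- transitions.p_loss
- utilities.u_preg_no_iud
- costs.c_consultation_no_iud
- costs.c_unintended_pregnancy
- scenarios.Pernambuco.n_professionals
- scenarios.Scenario 1.n_professionals
- scenarios.Scenario 2.n_professionals
- scenarios.Scenario 3.n_professionals
distributions:
- param: costs.c_training_per_professional
  family: gamma
  mean: 1820.38
  sd: 182.038
- param: costs.c_insertion
  family: gamma
  mean: 91.02
  sd: 9.102
- param: costs.c_consultation_no_iud
  family: gamma
  mean: 10.0
  sd: 1.0
- param: costs.c_unintended_pregnancy
  family: gamma
  mean: 3000.0
  sd: 300.0
- param: utilities.u_iud_no_preg
  family: fixed
  mean: 1.0
  sd: 0.0
- param: utilities.u_no_iud_no_preg
  family: beta
  mean: 0.8
  sd: 0.08000000000000002
- param: utilities.u_preg_no_iud
  family: beta
  mean: 0.7
  sd: 0.06999999999999999
- param: utilities.disutility_preg_iud
  family: beta
  mean: -0.1
  sd: 0.010000000000000002
- param: transitions.p_preg_no_iud
  family: beta
  mean: 0.14622990588362894
  sd: 0.014622990588362896
- param: transitions.p_preg_iud
  family: beta
  mean: 0.0006691236782786492
  sd: 6.691236782786491e-05
ranges:
- param: costs.c_training_per_professional
  low: 1456.304
  base: 1820.38
  high: 2184.456
- param: costs.c_insertion
  low: 72.816
  base: 91.02
  high: 109.22399999999999
- param: costs.c_consultation_no_iud
  low: 8.0
  base: 10.0
  high: 12.0
- param: costs.c_unintended_pregnancy
  low: 2400.0
  base: 3000.0
  high: 3600.0
- param: utilities.u_iud_no_preg
  low: 0.8
  base: 1.0
  high: 1.0
- param: utilities.u_no_iud_no_preg
  low: 0.6400000000000001
  base: 0.8
  high: 0.96
- param: utilities.u_preg_no_iud
  low: 0.5599999999999999
  base: 0.7
  high: 0.84
- param: utilities.disutility_preg_iud
  low: -0.12
  base: -0.1
  high: -0.08000000000000002
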