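# Registry of compared belief-updating model variants.
# omega2_structure: fixed (= 1) | shared | conditionwise
- name: ideal
- name: prior_only
  omega1_free: true
- name: likelihood_shared
  omega2_structure: shared
- name: likelihood_conditionwise
  omega2_structure: conditionwise
- name: prior_likelihood_shared
  omega1_free: true
  omega2_structure: shared
- name: prior_likelihood_conditionwise
  omega1_free: true
  omega2_structure: conditionwise
- name: no_prior
  heuristic: no_prior
- name: observed_proportion
  heuristic: observed_proportion
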