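# Fully invented demonstration model for tests and examples.
# One compartment, allometric + maturation clearance; round numbers
# throughout so expected values are easy to derive by hand.
drug_name: demo
n_compartments: 1
parameter_names: [CL, V]
typical_values:
  CL: 0.20   # L/h at 1.0 kg, maturation complete
  V: 0.50    # L at 1.0 kg
covariate_effects:
  - {target_parameter: CL, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 0.75}
  - {target_parameter: CL, covariate: pma, kind: sigmoid_maturation, pma50: 40.0, hill: 3.0}
  - {target_parameter: V, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 1.0}
omega:
  CL: 0.09
  V: 0.09
residual_error:
  proportional_sd: 0.15
  additive_sd: 0.2
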