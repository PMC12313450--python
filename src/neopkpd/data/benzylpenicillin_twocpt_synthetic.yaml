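# SYNTHETIC benzylpenicillin neonatal population-PK parameter set.
#
# Structure: two-compartment IV model with PMA-dependent clearance maturation
# and allometric scaling to birth weight (reference 1.0 kg, a very-preterm
# neonate). The NUMERIC values are NOT transcribed from any published model:
# they are a synthetic stand-in chosen once from neonatal penicillin-G PK
# literature ranges (half-life ~2-5 h, central V ~0.45 L/kg). Edit this file
# to substitute estimates from a published model.
drug_name: benzylpenicillin
n_compartments: 2
parameter_names: [CL, V, Q, V2]
typical_values:
  CL: 0.50   # L/h at 1.0 kg, maturation complete
  V: 0.45    # L at 1.0 kg (central)
  Q: 0.20    # L/h at 1.0 kg
  V2: 0.30   # L at 1.0 kg (peripheral)
covariate_effects:
  - {target_parameter: CL, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 0.75}
  - {target_parameter: CL, covariate: pma, kind: sigmoid_maturation, pma50: 42.0, hill: 3.0}
  - {target_parameter: V, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 1.0}
  - {target_parameter: Q, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 0.75}
  - {target_parameter: V2, covariate: birth_weight, kind: allometric_power, reference: 1.0, exponent: 1.0}
omega:
  CL: 0.10
  V: 0.15
residual_error:
  proportional_sd: 0.20
  additive_sd: 0.3   # mg/L
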