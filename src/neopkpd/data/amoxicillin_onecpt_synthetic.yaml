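# SYNTHETIC amoxicillin neonatal population-PK parameter set.
#
# Structure: one-compartment IV model with PMA- and PNA-dependent clearance
# maturation and allometric scaling to birth weight (reference 1.75 kg, the
# approximate cohort median). The NUMERIC values below are NOT transcribed
# from any published model: they are a synthetic stand-in chosen once from
# neonatal amoxicillin PK literature ranges (half-life ~5-12 h across
# GA 24-42 weeks, V ~0.65 L/kg). Edit this file to substitute estimates from
# a published model.
drug_name: amoxicillin
n_compartments: 1
parameter_names: [CL, V]
typical_values:
  CL: 0.41   # L/h at 1.75 kg, maturation complete
  V: 1.14    # L at 1.75 kg (~0.65 L/kg)
covariate_effects:
  - {target_parameter: CL, covariate: birth_weight, kind: allometric_power, reference: 1.75, exponent: 0.75}
  - {target_parameter: CL, covariate: pma, kind: sigmoid_maturation, pma50: 45.0, hill: 3.4}
  - {target_parameter: CL, covariate: pna, kind: linear, reference: 0.0, slope: 0.11}   # per day
  - {target_parameter: V, covariate: birth_weight, kind: allometric_power, reference: 1.75, exponent: 1.0}
omega:
  CL: 0.12   # variance of log-normal BSV
  V: 0.08
residual_error:
  proportional_sd: 0.20
  additive_sd: 0.5   # mg/L
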