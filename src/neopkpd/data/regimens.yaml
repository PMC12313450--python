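# Regimen catalog. Each regimen is a list of mutually exclusive strata over
# birth weight (kg), GA (weeks) and PNA (days); bounds are half-open
# (min <= x < max), omitted bounds are open. Doses are per kg; 'iu' doses are
# converted at 0.6 ug/IU. All intermittent administrations are 5-min infusions
# starting at birth (t = 0).
#
# The catalog ships the Dutch Pediatric Formulary (DPF) sepsis regimens and
# the two optimized benzylpenicillin regimens. Further formulary regimens
# (ANMF, BNFC, Lexicomp, NeoFax, NF, NDPGH, SwissPedDose) can be added here
# using the same schema.
regimens:
  - name: dpf
    drug: amoxicillin
    rules:
      - {dose_per_kg: 25, unit: mg, interval_h: 12, bw_max_kg: 2.0}
      - {dose_per_kg: 25, unit: mg, interval_h: 8, bw_min_kg: 2.0}
  - name: dpf
    drug: benzylpenicillin
    rules:
      - {dose_per_kg: 25000, unit: iu, interval_h: 12, bw_max_kg: 2.0}
      - {dose_per_kg: 25000, unit: iu, interval_h: 8, bw_min_kg: 2.0}
  - name: ga-banded
    drug: benzylpenicillin
    rules:
      - {dose_per_kg: 30000, unit: iu, interval_h: 12, ga_max_weeks: 28}
      - {dose_per_kg: 30000, unit: iu, interval_h: 8, ga_min_weeks: 28, ga_max_weeks: 36}
      - {dose_per_kg: 30000, unit: iu, interval_h: 6, ga_min_weeks: 36}
  - name: continuous
    drug: benzylpenicillin
    rules:
      # DPF-based total daily dose as continuous infusion + 16.7% loading dose
      - {dose_per_kg: 50000, unit: iu, mode: continuous, loading_fraction: 0.167, bw_max_kg: 2.0}
      - {dose_per_kg: 75000, unit: iu, mode: continuous, loading_fraction: 0.167, bw_min_kg: 2.0}
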