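# SYNTHETIC per-GA-week birth-weight percentiles (kg), sex-pooled, shaped
# after published neonatal growth charts. A log-normal is fitted per week
# from the 3rd/50th/97th percentiles. Edit to substitute chart values.
birth_weight_percentiles:
  - {ga_week: 24, p3_kg: 0.46, p50_kg: 0.65, p97_kg: 0.89}
  - {ga_week: 25, p3_kg: 0.53, p50_kg: 0.75, p97_kg: 1.03}
  - {ga_week: 26, p3_kg: 0.61, p50_kg: 0.86, p97_kg: 1.18}
  - {ga_week: 27, p3_kg: 0.69, p50_kg: 0.98, p97_kg: 1.35}
  - {ga_week: 28, p3_kg: 0.79, p50_kg: 1.12, p97_kg: 1.54}
  - {ga_week: 29, p3_kg: 0.90, p50_kg: 1.27, p97_kg: 1.75}
  - {ga_week: 30, p3_kg: 1.02, p50_kg: 1.44, p97_kg: 1.98}
  - {ga_week: 31, p3_kg: 1.16, p50_kg: 1.63, p97_kg: 2.24}
  - {ga_week: 32, p3_kg: 1.31, p50_kg: 1.84, p97_kg: 2.52}
  - {ga_week: 33, p3_kg: 1.48, p50_kg: 2.07, p97_kg: 2.82}
  - {ga_week: 34, p3_kg: 1.67, p50_kg: 2.32, p97_kg: 3.14}
  - {ga_week: 35, p3_kg: 1.87, p50_kg: 2.58, p97_kg: 3.46}
  - {ga_week: 36, p3_kg: 2.07, p50_kg: 2.85, p97_kg: 3.77}
  - {ga_week: 37, p3_kg: 2.27, p50_kg: 3.10, p97_kg: 4.05}
  - {ga_week: 38, p3_kg: 2.46, p50_kg: 3.32, p97_kg: 4.28}
  - {ga_week: 39, p3_kg: 2.62, p50_kg: 3.50, p97_kg: 4.46}
  - {ga_week: 40, p3_kg: 2.75, p50_kg: 3.65, p97_kg: 4.59}
  - {ga_week: 41, p3_kg: 2.85, p50_kg: 3.75, p97_kg: 4.69}
  - {ga_week: 42, p3_kg: 2.91, p50_kg: 3.82, p97_kg: 4.76}
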