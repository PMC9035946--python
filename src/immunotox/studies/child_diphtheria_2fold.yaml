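# Child cohort, two-dose diphtheria immunization; paired-seed contrast of a
# reference constant serum exposure C0 against 2*C0 to estimate the percent
# difference in the anti-diphtheria antibody endpoint per exposure doubling.
# The endpoint is antigen-specific IgG sampled 60 days after the second dose.
name: child-diphtheria-2fold
population: child
n: 50
exposure:
  chemical: PFOA
  serum_ng_ml: 10.0          # C0; the contrast arm runs at 2 * C0
  contrast: twofold
schedule:
  duration_days: 90
  sampling_day: 90
  endpoint_antigen: diphtheria
  events:
    - {day: 0, type: VACCINE_DOSE, antigen: diphtheria, dose: 2000}
    - {day: 30, type: VACCINE_DOSE, antigen: diphtheria, dose: 2000}
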