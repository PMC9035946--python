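# Influenza study: 411 adult digital twins with heterogeneous serum PFOA,
# all receiving one influenza (H1N1) vaccination; patients are split into 4
# exposure quartiles and anti-H1N1 titers compared across quartiles.
name: influenza-quartiles
population: adult
n: 411
exposure:
  chemical: PFOA
  per_patient: true
schedule:
  duration_days: 40
  sampling_day: 40
  endpoint_antigen: h1n1
  events:
    - {day: 0, type: VACCINE_DOSE, antigen: h1n1, dose: 2000}
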