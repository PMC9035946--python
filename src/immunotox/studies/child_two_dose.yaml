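# Childhood-vaccination study: children with heterogeneous serum PFAS
# levels (each patient's own PFOA feature), two-dose schedule with three
# vaccine antigens; analysed by exposure-response rank correlation of the
# antigen-specific titers.
name: child-two-dose
population: child
n: 100
exposure:
  chemical: PFOA
  per_patient: true          # each patient's own serum level, constant in time
schedule:
  duration_days: 90
  sampling_day: 90
  endpoint_antigen: diphtheria
  events:
    - {day: 0, type: VACCINE_DOSE, antigen: hib, dose: 1200}
    - {day: 0, type: VACCINE_DOSE, antigen: tetanus, dose: 1200}
    - {day: 0, type: VACCINE_DOSE, antigen: diphtheria, dose: 1200}
    - {day: 30, type: VACCINE_DOSE, antigen: hib, dose: 1200}
    - {day: 30, type: VACCINE_DOSE, antigen: tetanus, dose: 1200}
    - {day: 30, type: VACCINE_DOSE, antigen: diphtheria, dose: 1200}
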