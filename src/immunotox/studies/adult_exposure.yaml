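# Two cohorts of 100 adults (ages 18-60): one exposed to PFOA reaching a
# constant serum concentration of 10 ng/ml at time 0, one unexposed; both
# receive two generic bacterial challenges at day 20 and day 100.
name: adult-exposure
population: adult
n: 100
exposure:
  chemical: PFOA
  serum_ng_ml: 10.0
  contrast: unexposed        # paired-seed comparison arm at 0 ng/ml
schedule:
  duration_days: 130
  sampling_day: null         # endpoint = peak antigen-specific titer
  events:
    - {day: 20, type: BACTERIAL_CHALLENGE, antigen: generic-bacterium, dose: 2000}
    - {day: 100, type: BACTERIAL_CHALLENGE, antigen: generic-bacterium, dose: 2000}
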