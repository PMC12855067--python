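# Nearly unaffected control: ~1.5 discharges per 24 h (state rates are the
# affected-strain rates scaled by 1.5/93).
name: ola_like
daily_event_mean: 1.5
state_rates:
  SWS: 0.117742
  WAKE: 0.006935
  REM: 0.012419
circadian_beta: 1.24
acrophase_h: 12.0
awakening_hazard: 3.0
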