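# Virtually discharge-free control.
name: c57_like
daily_event_mean: 0.0
state_rates:
  SWS: 0.0
  WAKE: 0.0
  REM: 0.0
circadian_beta: 1.24
acrophase_h: 12.0
awakening_hazard: 1.0
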