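# Affected strain: ~93 spike-and-wave discharges per 24 h, ~94% in SWS,
# circadian intensity peaking at ZT12, 3x awakening hazard after an
# SWD-containing SWS epoch.
name: jax_like
daily_event_mean: 93.0
state_rates:   # events per hour spent in state
  SWS: 7.3
  WAKE: 0.43
  REM: 0.77
circadian_beta: 1.24
acrophase_h: 12.0
awakening_hazard: 3.0
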