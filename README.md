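# somnispike

Detection and sleep-context analysis of spontaneous spike-and-wave
discharges (SWDs) in rodent EEG/EMG, with a calibrated synthetic-data
generator for end-to-end validation.

Absence-epilepsy-like discharges in mice — brief (~2 s) high-voltage
oscillations with a ~6.7 Hz fundamental and a ~13.3 Hz second spectral
component — occur almost exclusively during slow-wave sleep (SWS), follow a
circadian rhythm peaking near the light/dark transition, and are followed by
an elevated probability of awakening. `somnispike` implements the full
analysis chain needed to quantify this phenotype from 24-h recordings:

* **I/O** — EDF signals (with a JSON sidecar carrying the Zeitgeber
  anchor), CSV hypnograms (10-s epochs, WAKE/SWS/REM/ARTIFACT), CSV event
  tables.
* **Preprocessing** — zero-phase acquisition-chain filters (EEG 0.3–70 Hz,
  EMG high-pass 10 Hz, optional 50-Hz notch) and robust amplitude-based
  artifact tagging.
* **Sleep scoring** — a transparent three-rule stager (EMG tone → delta
  fraction → theta/delta ratio) with per-recording auto-calibrated
  thresholds.
* **SWD detection** — an amplitude criterion (envelope ≥ 1.5 × a rolling,
  state-conditional background) plus a cycle criterion (≥ 4 rhythmic
  supra-threshold peaks), with zero-crossing boundary marking and a
  review-export stage for human curation.
* **Event spectra** — per-event Welch PSDs (2-s Hann, 0.5-s overlap)
  normalized against the whole-recording artifact-free PSD, expressed as
  percentage of total power, with sub-bin extraction of the two
  characteristic peaks.
* **Sleep metrics** — time in state, bouts, fragmentation, transition-pair
  frequencies, per-state event rates, and the conditional probability of a
  state transition after discharge-containing vs discharge-free epochs.
* **Circadian statistics** — hourly histograms and rates per minute of SWS,
  the Rayleigh uniformity test (Zar's p approximation), and a fixed-period
  24-h cosinor fit (MESOR, amplitude, acrophase, zero-amplitude F test).
* **Synthetic data** — 24-h EEG/EMG with exact ground truth: a two-phase
  Markov sleep model, per-state Poisson discharge rates under an
  exponential-cosine circadian gain, an awakening hazard after
  discharge-containing epochs, and state-dependent background synthesis.
  Shipped strain profiles: `jax_like` (~93 events/day), `ola_like`
  (~1.5/day), `c57_like` (none).

The model at the core of the generator: discharges arrive as an
inhomogeneous Poisson process with intensity

    lambda(t) = lambda_state(t) * exp(beta * cos(2*pi*(t - phi)/24)) / I0(beta)

(`lambda_SWS = 7.3/h`, `beta = 1.24`, `phi = ZT 12`), and each
discharge-containing SWS epoch multiplies the next SWS→WAKE transition
probability by a hazard of 3. Every analysis stage is validated by
recovering these planted parameters.

## Worked example

```python
import somnispike as sp

# simulate one affected animal-day (100 Hz keeps this fast)
profile = sp.get_profile("jax_like")
rec, truth_hyp, truth_events = sp.simulate_recording(
    profile, duration_h=24, fs=100, seed=1)

# filter, score sleep, detect discharges
filt = sp.apply_acquisition_filters(
    rec, sp.FilterSpec(eeg_lp_hz=40, notch_hz=None))
hyp = sp.score_recording(filt)
hyp = sp.tag_artifacts(filt, hyp)
events = sp.detect_candidates(filt, hyp=hyp)

print(f"detected {len(events)} discharges "
      f"(truth: {len(truth_events)})")
print(sp.evaluate_detection(events, truth_events))

events, shares = sp.attribute_events(events, hyp)
print({s: round(v, 1) for s, v in shares['shares_pct'].items()})
```

Output:

```
detected 94 discharges (truth: 96)
{'n_truth': 96, 'n_detected': 94, 'true_positives': 94, 'recall': 0.9791666666666666, 'precision': 1.0, 'onset_mae_s': 0.11235075734800902}
{'WAKE': 3.2, 'SWS': 93.5, 'REM': 3.2}
```

The detector recovers 94 of 96 planted discharges with no false positives
and ~0.1-s onset accuracy; 93.5 % of detected events start in SWS,
matching the planted per-state rates. Downstream,
`sp.circadian_summary(events, hyp)` yields the hourly histogram, a Rayleigh
p-value ≈ 1e-13 (events are far from uniformly distributed over the day)
and a cosinor acrophase near ZT 12.

A command-line interface mirrors the library:

```bash
somnispike simulate --profile jax_like --hours 24 --seed 1 --out data/
somnispike score data/jax_like_seed1.edf -o hyp.csv
somnispike detect data/jax_like_seed1.edf --hyp hyp.csv --no-notch -o events.csv
somnispike circadian events.csv hyp.csv -o circ.json
somnispike run --config cohort.yaml   # full cohort pipeline + summary CSV
```

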