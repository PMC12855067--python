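# Methods

`somnispike` analyzes 24-h mouse EEG/EMG recordings for spontaneous
spike-and-wave discharges (SWDs) and their relation to sleep. Because no
public recordings of this kind exist with curated ground truth, the package
pairs every analysis stage with a calibrated synthetic generator, so that
each stage can be validated as a parameter-recovery problem: the generator
plants known structure, the pipeline must find it.

## Signal model and preprocessing

Recordings carry at least one EEG channel and one EMG channel in microvolts,
with a Zeitgeber anchor (`start_zt`, hours since lights-on) and the duration
of the lights-on block (12 h by default). All primary timestamps are seconds
from recording start; ZT is always derived. Event intervals are half-open
`[onset, offset)` and scoring epoch `e` covers `[10e, 10e+10)` s.

The acquisition-chain filter bank is EEG band-pass 0.3–70 Hz, EMG high-pass
10 Hz, optional 50-Hz notch (Butterworth order 4, notch Q = 30). Filters run
forward–backward (zero phase): the analog chain they emulate was causal, but
event boundary timing downstream must not carry group delay. When the
low-pass corner would exceed Nyquist (simulations at 100 Hz), the pipeline
caps it at 0.4 × fs; the notch is enabled only when mains interference is
actually present.

Artifact epochs are tagged by a robust amplitude rule — samples beyond
10 × the recording-wide median absolute deviation for ≥ 0.5 s cumulative
within an epoch, or clipped samples — standing in for manual tagging. The
rule is deliberately conservative; pre-tagging labels are kept in a shadow
column, tagged epochs are excluded from every downstream denominator, and an
ARTIFACT label is never reverted.

## Synthetic data generator

Three layers are co-simulated per 10-s epoch.

**Vigilance states.** An inhomogeneous Markov chain over WAKE/SWS/REM with
separate lights-on and lights-off transition matrices. Direct WAKE→REM
transitions are forbidden. The default matrices were calibrated once, by
direct simulation, to realize ≈ 48 % SWS and ≈ 4 % REM over 24 h, sleep
concentrated in lights-on (≈ 60 % vs ≈ 35 % SWS), and bout durations of
1.5–4 min (polyphasic sleep). The calibration jointly targeted the
post-discharge transition-probability ratio (below); exit rates were kept
comparable across states because the measured coupling ratio degrades when
wake bouts are much longer than sleep bouts.

**Discharges.** SWDs arrive as a Poisson process with intensity
`lambda_state x c(t)`, where `lambda` is a per-state rate in events per hour
in state (defaults 7.3 SWS / 0.43 WAKE / 0.77 REM for the affected profile,
scaled by 1.5/93 for the nearly unaffected control, zero for the clean
control) and `c(t) = exp(beta cos(2 pi (t - acrophase)/24)) / I0(beta)` is a
positive circadian gain normalized to daily mean 1 (`I0` is the modified
Bessel function). `beta = 1.24` makes the intensity ≈ 4-fold higher at
ZT 11.5 than at ZT 5.5; the acrophase sits at the light/dark transition
(ZT 12). Under the realized state composition this yields ≈ 91 events/day,
≈ 93 % of them in SWS. An epoch containing any part of a discharge
multiplies the SWS→WAKE probability of the next transition by the awakening
hazard (default 3, rows renormalized), which produces a post-discharge
transition-probability ratio of ≈ 2.2–2.4.

**Signals.** Background EEG is a state-gated mixture of three components:
slow-wave noise (0.5–3 Hz), flat broadband noise (0.5–45 Hz), and a theta
rhythm. Per-state gains (µV RMS) are SWS 45/20/5, WAKE 3/13/4, REM 3/8/10;
gain profiles are smoothed over 0.5 s across epoch boundaries. The theta
component is synthesized as a sustained oscillation whose instantaneous
frequency wanders around 7 Hz (Ornstein–Uhlenbeck jitter, ±0.6 Hz, 2-s
correlation time) rather than as band-limited noise: physiological theta is
a continuous rhythm with a nearly constant envelope, and a Rayleigh-
fluctuating noise envelope would spuriously trigger any amplitude-based
event detector during REM. EMG is 10–45 Hz noise with state-dependent RMS
(WAKE 30, SWS 8, REM 4 µV).

Each SWD is `sin(2 pi f0 t) + 0.45 sin(2 pi f1 t)` under a raised-cosine
envelope (0.1-s tapers), with `f0 = 6.73` and `f1 = 13.28` Hz set
independently (the empirical second component of such discharges is not an
exact harmonic), normalized to unit peak and scaled to 2.5 × the RMS of the
background EEG it is inserted into. Durations are log-normal with
arithmetic mean 2.0 s (log-SD 0.25), truncated to `[4/f0, 6]` s so the
4-cycle detection criterion is satisfiable by construction. Events may
spill into the next epoch; their attributed state is the onset state.
Events never overlap.

One seeded NumPy generator drives the state/event layer and a second,
derived from the same seed, drives signal synthesis — fixtures are
bit-reproducible.

**What the generator does not emulate** (and hence what passing tests do
not show about real data): electrode and movement artifacts beyond
state-dependent variance, the precursor oscillations that sometimes precede
real discharges, spike–wave asymmetry within a cycle, inter-animal
variability of background amplitude or waveform morphology, and scorer
disagreement. Real recordings will degrade the stager and detector in ways
this suite cannot measure.

## Sleep scoring

A transparent three-rule epoch classifier over Welch band powers (2-s Hann
windows, 0.5-s overlap — the same estimator as the event spectra): WAKE if
EMG RMS exceeds its threshold; else SWS if the delta (0.5–4 Hz) fraction of
0.5–30 Hz power reaches its threshold; else REM if theta/delta (5–9 over
0.5–4 Hz) ≥ 2; else SWS. "Auto" thresholds are calibrated per recording:
the EMG cut is the log-space midpoint of a 2-class 1-D k-means on log EMG
RMS (falling back to fixed thresholds, with a warning, when the clusters
are not separated), and the delta cut is the 60th percentile of delta
fractions among low-EMG epochs. Epochs containing SWDs are scored from the
same features — the discharge raises theta and total power, but the
rule order (delta test before the REM test, SWS as the default) keeps such
epochs in SWS. Scoring without an EMG channel is refused rather than
guessed. Against generator truth the stager agrees on ≥ 97 % of epochs;
the ≥ 85 % bound asserted in the suite leaves margin for less separable
parameter settings.

## Discharge detection

Two-stage design. The permissive pass band-passes the EEG (4–20 Hz,
Butterworth order 8, zero phase), takes the analytic (Hilbert) envelope,
smooths it with a 2-s moving average, and marks runs where the smoothed
envelope reaches 1.5 × a rolling background level; runs closer than 0.3 s
merge. The acceptance filter then requires at least 4 supra-threshold
oscillation peaks whose successive intervals lie within the band's period
range (0.05–0.25 s); maxima closer than the shortest admissible period
count as one cycle. Boundaries extend to the nearest zero crossings beyond
the first and last counted peak. A review-export stage (per-event trace
snippets plus an accept/reject template) stands in for the visual curation
such detectors normally require.

The background level is the rolling median of the smoothed envelope over
60 s of *same-state*, artifact-free blocks (1-s resolution), with a ±2-s
running-max guard at state boundaries. Three design points deserve
explanation:

* **State-conditional background.** Rodent EEG amplitude is strongly
  state-dependent (SWS ≈ 3× WAKE here). A state-blind 60-s median makes
  every short SWS bout inside wakefulness exceed 1.5 × background for its
  entire duration — hundreds of false events per day. Conditioning the
  background on the scored state removes this failure mode entirely; the
  boundary guard handles envelope bleed across scored-state edges. Without
  a hypnogram the estimator falls back to the state-blind rolling median,
  which is adequate for stationary signals.
* **2-s envelope smoothing.** A discharge sustains its envelope for its
  whole duration, while background envelope excursions decorrelate within a
  fraction of a second; averaging over ~2 s separates the two populations
  by orders of magnitude in exceedance probability. The smoothing biases
  against events shorter than ~1 s at low amplitude margins, which at the
  calibrated signal-to-background ratio costs a small fraction of WAKE
  events.
* **4-Hz band floor.** Slow-wave activity bleeds through any realizable
  filter skirt at a 3-Hz edge as a narrow sliver whose envelope fluctuates
  over seconds — too slowly for any smoothing to average out. Raising the
  floor to 4 Hz (still > 2.5 Hz below the 6.7-Hz fundamental) removes the
  sliver; the cycle-period bounds follow the band.

At the calibrated conditions the detector achieves recall ≈ 0.98,
precision ≈ 0.99, onset error ≈ 0.08 s, and zero false positives per day
on discharge-free recordings. The threshold factor (1.5) and cycle minimum
(4) are the discharge definition and are never altered; detection is
monotone in the threshold factor and invariant to rescaling the recording.

## Event spectra

Per-event Welch PSD (2-s Hann, 0.5-s overlap; events shorter than one
window use a single full-length window; FFTs zero-padded to ≤ 0.1 Hz native
spacing), divided bin-wise by the PSD of the total artifact-free EEG
(same estimator laid back-to-back; the ratio floor is the reference's 1st
percentile), interpolated onto a fixed 0.5–30 Hz grid at 0.1 Hz, and
rescaled to percentage of total (summing to 100). Peaks are the two most
prominent local maxima in 3–20 Hz after subtracting a median-filtered
baseline, refined by quadratic interpolation over the three bins around
each maximum — a 2-s window alone has 0.5-Hz bins and could not report a
6.73-Hz peak, so sub-bin estimation is required. For noiseless sinusoids
the chain is exact to ±0.02 Hz. On full simulations the cohort mean peaks
sit ~0.1 Hz below the planted frequencies because the reference spectrum
contains a theta bump near 7 Hz that tilts the normalized ratio; the bias
is well inside the reported between-animal spread. Both per-event-mean and
per-mouse-mean-spectrum peak statistics are computed, since the averaging
order is a free choice.

## Sleep architecture and interaction

Bouts are maximal same-label runs; transitions are adjacent-label changes
among artifact-free epochs. ARTIFACT epochs break runs without creating
transitions (a WAKE–ARTIFACT–SWS sequence contributes none), so artifact
exclusion can never inflate fragmentation; the run-length identity
`transitions = bouts − contiguous segments` is asserted on every analysis.
Events are attributed to the state of their onset epoch; per-state rates
divide by artifact-free hours in state. For discharge–transition coupling,
an epoch "contains" a discharge if any event overlaps it (an onset-only
variant is available); the post-SWD vs post-clean transition-probability
ratio is reported with a seeded 1,000-resample bootstrap interval as
supplementary output. Cohort-level fragmentation–discharge coupling uses
Pearson correlation with the two-sided t-test (n − 2 df).

## Circadian statistics

Hourly ZT histograms report counts and counts per minute of SWS in each
`[h, h+1)` bin. The Rayleigh test uses phases `2 pi ZT/24` and the
small-sample-corrected p-value
`p = exp(sqrt(1 + 4n + 4(n² − Rn²)) − (1 + 2n))` (Zar, *Biostatistical
Analysis*, 1999), pinned because approximations differ between texts; its
null calibration is enforced by a uniformity test over 1,000 seeded
replicates (fewer replicates cannot statistically resolve the asserted
0.05 Kolmogorov–Smirnov bound: the expected D for R replicates of an exact
p-value is ≈ 0.86/√R). The cosinor is ordinary least squares of
`y = M + b_c cos(wt) + b_s sin(wt)` at a fixed 24-h period on hourly binned
counts (an events-as-points alternative exists), reported as MESOR,
amplitude `A = hypot(b_c, b_s)`, and acrophase `phi = atan2(b_s, b_c)/w`
— the peak time of the fitted curve `M + A cos(w(t − phi))`, which makes
the fit time-shift equivariant — plus the zero-amplitude F test on
(2, n − 3) df. Days are analyzed separately; pooling requires explicit
concatenation.

## Problem sizes and determinism

Simulations run at 100 Hz (the analysis pipeline is rate-agnostic; filter
corners adapt as described above). The validation cohorts are 8 affected
animal-days for detection/spectral/circadian recovery, 20 days for staging
composition, 50 control days for the low-rate regime, and 25–50
hypnogram-level days for coupling properties, all with fixed seed lists.
Every stochastic stage takes an explicit seed; identical configuration
yields byte-identical outputs.

## Known limitations

The stager is a surrogate for visual scoring and its thresholds assume a
bimodal EMG distribution; the detector's background model assumes the
hypnogram is at least roughly correct (garbage staging degrades the
state-conditional background); the coupling analysis is epoch-resolution
and cannot see sub-10-s arousals; the cosinor is single-component with a
fixed 24-h period; and the correlation between per-animal discharge counts
and fragmentation has low statistical power at realistic cohort sizes
because the awakening hazard adds only ~1 transition per 11 discharges
against a noisy baseline — the suite therefore asserts a positive mean
correlation across replicate cohorts rather than per-cohort significance.
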