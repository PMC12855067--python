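"""Shared fixtures: small synthetic recordings and the cohort used by the
acceptance suite.  Everything is generated programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest

import somnispike as sp
from somnispike import pipeline
from somnispike.types import Channel, Hypnogram, SignalRecording


@pytest.fixture(scope="session")
def noise_recording():
    """10 min of stationary Gaussian noise on EEG and EMG at 200 Hz."""
    rng = np.random.default_rng(42)
    fs = 200.0
    n = int(600 * fs)
    return SignalRecording(
        channels=[Channel("EEG_frontal", "EEG_frontal", rng.standard_normal(n)),
                  Channel("EMG_nuchal", "EMG", 0.5 * rng.standard_normal(n))],
        fs=fs)


@pytest.fixture()
def short_recording():
    """60-s two-channel recording with deterministic content."""
    fs = 200.0
    t = np.arange(int(60 * fs)) / fs
    eeg = 50 * np.sin(2 * np.pi * 2.0 * t)
    emg = 10 * np.sin(2 * np.pi * 25.0 * t)
    return SignalRecording(
        channels=[Channel("EEG_frontal", "EEG_frontal", eeg),
                  Channel("EMG_nuchal", "EMG", emg)],
        fs=fs, start_zt=3.5)


def inject_burst(rec: SignalRecording, onset_s: float, duration_s: float,
                 amplitude: float, f0: float = 6.7, f1: float | None = None,
                 amp_ratio: float = 0.0) -> SignalRecording:
    """Copy of ``rec`` with a sinusoidal burst added to the EEG channel."""
    spec = sp.SWDWaveformSpec(f0_hz=f0, f1_hz=f1 or 2 * f0, amp_ratio=amp_ratio,
                              taper_s=0.05)
    w = spec.waveform(duration_s, rec.fs)
    eeg = rec.eeg().data.copy()
    i0 = int(round(onset_s * rec.fs))
    eeg[i0:i0 + len(w)] += amplitude * w
    chans = [Channel(c.name, c.role, eeg if c.role == rec.eeg().role else c.data.copy())
             for c in rec.channels]
    return SignalRecording(chans, rec.fs, rec.start_zt, rec.light_period_h)


@pytest.fixture(scope="session")
def jax_cohort():
    """Eight simulated affected-strain animal-days (seeds 1-8), run through
    the full pipeline.  Shared by the acceptance tests; takes ~2 min."""
    cfg = pipeline.PipelineConfig(profile="jax_like", seeds=list(range(1, 9)),
                                  fs=100.0)
    results = []
    for seed in cfg.seeds:
        results.append(pipeline.run_animal(cfg, seed))
    return results
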