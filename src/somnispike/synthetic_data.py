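"""Synthetic 24-h mouse EEG/EMG with known ground truth.

The generator is phenomenological, not biophysical: it reproduces the
statistical structure a sleep-EEG pipeline cares about, so that every
downstream stage (scoring, detection, spectra, circadian statistics) can be
validated against exact ground truth.

Three layers are co-simulated epoch by epoch (10-s epochs):

1. **Vigilance states** follow an inhomogeneous Markov chain over
   WAKE/SWS/REM with separate lights-on and lights-off transition matrices,
   calibrated so a 24-h day holds roughly 50 % SWS and 5 % REM with sleep
   concentrated in lights-on.  REM is reachable only from SWS.
2. **Spike-and-wave discharges (SWDs)** arrive as a Poisson process whose
   intensity is a per-state rate (events per hour in state) multiplied by a
   positive circadian gain ``c(t) = exp(beta * cos(2*pi*(t - acrophase)/24))``
   normalized to daily mean 1.  An affected-strain day carries ~93 events,
   ~94 % of them in SWS.  An SWD-containing SWS epoch multiplies the
   SWS->WAKE probability of the next transition by ``awakening_hazard``
   (row renormalized), producing the elevated awakening probability after
   discharge-containing epochs.
3. **Signals**: state-dependent mixtures of band-limited Gaussian noise for
   the EEG background (slow-wave-heavy in SWS, low-voltage broadband in
   WAKE, theta-dominant in REM) and state-dependent EMG tone.  Each SWD is a
   two-component sinusoid (fundamental ~6.7 Hz plus an independent ~13.3 Hz
   component) under a raised-cosine envelope, scaled to ``k`` times the RMS
   of the surrounding background EEG.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, special

from .types import (Channel, Hypnogram, SignalRecording, STATES,
                    ValidationError, make_events)

EPOCH_LEN_S = 10.0
_STATE_IDX = {s: i for i, s in enumerate(STATES)}  # WAKE=0, SWS=1, REM=2


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class StrainProfile:
    """Event-generation parameters for one mouse strain.

    ``state_rates`` are SWD intensities per hour spent in each state;
    ``daily_event_mean`` is the nominal daily total they were calibrated to
    produce under the default hypnogram composition.
    """

    name: str
    daily_event_mean: float
    state_rates: dict[str, float]
    circadian_beta: float = 1.24
    acrophase_h: float = 12.0
    awakening_hazard: float = 3.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.state_rates.values()):
            raise ValidationError("state rates must be non-negative")
        if self.awakening_hazard < 1:
            raise ValidationError("awakening hazard must be >= 1")

    def circadian_gain(self, zt_h: float | np.ndarray) -> float | np.ndarray:
        """Multiplicative intensity c(t) > 0, normalized to daily mean 1
        (the mean of exp(beta*cos) over a cycle is the Bessel function I0)."""
        raw = np.exp(self.circadian_beta
                     * np.cos(2 * np.pi * (np.asarray(zt_h) - self.acrophase_h) / 24.0))
        return raw / special.i0(self.circadian_beta)


@dataclass(frozen=True)
class SWDWaveformSpec:
    """Shape of an injected discharge.

    The two components sit at independently set frequencies (the measured
    second peak of real discharges is not an exact harmonic of the first).
    Durations are log-normal with arithmetic mean ``duration_mean_s``,
    truncated so every event satisfies the 4-cycle criterion by
    construction.  ``amplitude_factor`` scales the waveform peak to a
    multiple of the surrounding background EEG RMS.
    """

    f0_hz: float = 6.73
    f1_hz: float = 13.28
    amp_ratio: float = 0.45
    rel_phase: float = 0.0
    duration_mean_s: float = 2.0
    duration_log_sd: float = 0.25
    duration_max_s: float = 6.0
    amplitude_factor: float = 2.5
    taper_s: float = 0.1

    @property
    def duration_min_s(self) -> float:
        return 4.0 / self.f0_hz

    def sample_duration(self, rng: np.random.Generator) -> float:
        mu = np.log(self.duration_mean_s) - 0.5 * self.duration_log_sd**2
        for _ in range(100):
            d = float(rng.lognormal(mu, self.duration_log_sd))
            if self.duration_min_s <= d <= self.duration_max_s:
                return d
        return self.duration_mean_s

    def waveform(self, duration_s: float, fs: float) -> np.ndarray:
        """Unit-peak waveform sampled at ``fs``."""
        n = max(int(round(duration_s * fs)), 2)
        t = np.arange(n) / fs
        base = (np.sin(2 * np.pi * self.f0_hz * t)
                + self.amp_ratio * np.sin(2 * np.pi * self.f1_hz * t + self.rel_phase))
        n_taper = min(int(round(self.taper_s * fs)), n // 2)
        env = np.ones(n)
        if n_taper > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
            env[:n_taper] = ramp
            env[-n_taper:] = ramp[::-1]
        w = base * env
        peak = np.max(np.abs(w))
        return w / peak if peak > 0 else w


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 3):
        raise ValidationError("transition matrix must be 3x3 over (WAKE, SWS, REM)")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("transition matrix rows must be non-negative and sum to 1")
    if P[_STATE_IDX["WAKE"], _STATE_IDX["REM"]] > 0:
        raise ValidationError("direct WAKE->REM transitions are not allowed")
    return P


# Epoch-transition matrices calibrated so a 24-h day realizes roughly
# 48 % SWS / 4 % REM with sleep concentrated in lights-on, bout durations of
# a few minutes (polyphasic), and a post-SWD transition-probability ratio
# comfortably above 2 at the default awakening hazard.
_DEFAULT_ON = [
    [0.900, 0.100, 0.000],
    [0.042, 0.947, 0.011],
    [0.072, 0.030, 0.898],
]
_DEFAULT_OFF = [
    [0.952, 0.048, 0.000],
    [0.080, 0.9145, 0.0055],
    [0.092, 0.030, 0.878],
]


@dataclass(frozen=True)
class HypnogramModel:
    """Two 3x3 epoch-transition matrices over (WAKE, SWS, REM)."""

    lights_on: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_ON))
    lights_off: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_OFF))
    initial_state: str = "SWS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lights_on", _check_stochastic(self.lights_on))
        object.__setattr__(self, "lights_off", _check_stochastic(self.lights_off))
        if self.initial_state not in STATES:
            raise ValidationError(f"initial state must be one of {STATES}")

    def matrix_at(self, zt_h: float, light_period_h: float = 12.0) -> np.ndarray:
        return self.lights_on if (zt_h % 24.0) < light_period_h else self.lights_off


def simulate_hypnogram(model: HypnogramModel, duration_h: float, seed: int,
                       start_zt: float = 0.0, light_period_h: float = 12.0) -> Hypnogram:
    """Draw an epoch sequence from the inhomogeneous Markov chain."""
    if duration_h <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_h * 3600 / EPOCH_LEN_S))
    labels = np.empty(n, dtype="<U8")
    s = _STATE_IDX[model.initial_state]
    for e in range(n):
        zt = (start_zt + e * EPOCH_LEN_S / 3600.0) % 24.0
        labels[e] = STATES[s]
        P = model.matrix_at(zt, light_period_h)
        s = rng.choice(3, p=P[s])
    return Hypnogram(labels=labels, epoch_len_s=EPOCH_LEN_S, start_zt=start_zt,
                     light_period_h=light_period_h)


def simulate_ground_truth(profile: StrainProfile,
                          model: HypnogramModel | None = None,
                          waveform: SWDWaveformSpec | None = None,
                          duration_h: float = 24.0,
                          seed: int = 0,
                          start_zt: float = 0.0,
                          light_period_h: float = 12.0):
    """Co-simulate vigilance states and SWD events (no signal synthesis).

    Returns ``(Hypnogram, EventTable)``.  The event table carries exact
    half-open boundaries and the generating (onset) state.  An event may
    spill past its epoch; its attributed state is its onset state.
    """
    if duration_h <= 0:
        raise ValidationError("duration must be positive")
    model = model or HypnogramModel()
    waveform = waveform or SWDWaveformSpec()
    rng = np.random.default_rng(seed)

    n = int(round(duration_h * 3600 / EPOCH_LEN_S))
    labels = np.empty(n, dtype="<U8")
    onsets: list[float] = []
    offsets: list[float] = []
    ev_states: list[str] = []

    # per-epoch circadian gain at epoch midpoints, precomputed
    ep_mid_zt = (start_zt + (np.arange(n) + 0.5) * EPOCH_LEN_S / 3600.0) % 24.0
    gain = np.asarray(profile.circadian_gain(ep_mid_zt), dtype=float)
    rates = np.array([profile.state_rates.get(st, 0.0) for st in STATES])

    s = _STATE_IDX[model.initial_state]
    busy_until = -np.inf  # end of the latest event placed so far (no overlap)
    for e in range(n):
        zt = (start_zt + e * EPOCH_LEN_S / 3600.0) % 24.0
        labels[e] = STATES[s]
        lam = rates[s]
        k = rng.poisson(lam * gain[e] * EPOCH_LEN_S / 3600.0) if lam > 0 else 0
        ep_start = e * EPOCH_LEN_S
        placed_any = False
        for _ in range(k):
            dur = waveform.sample_duration(rng)
            for _attempt in range(20):
                onset = ep_start + rng.uniform(0, EPOCH_LEN_S)
                if onset >= busy_until and onset + dur <= n * EPOCH_LEN_S:
                    ok = all(not (onset < off and onset + dur > on)
                             for on, off in zip(onsets, offsets))
                    if ok:
                        onsets.append(onset)
                        offsets.append(onset + dur)
                        ev_states.append(STATES[s])
                        busy_until = max(busy_until, onset + dur)
                        placed_any = True
                        break
        P = model.matrix_at(zt, light_period_h)
        row = P[s]
        # the hazard keys on the epoch *containing* any discharge (an event
        # spilling over from the previous epoch counts), matching the
        # any-overlap reading of "an epoch containing an SWD episode"
        has_event = placed_any or busy_until > ep_start
        if has_event and STATES[s] == "SWS" and profile.awakening_hazard != 1.0:
            row = row.copy()
            row[_STATE_IDX["WAKE"]] *= profile.awakening_hazard
            row /= row.sum()
        u = rng.random()
        s = int(np.searchsorted(np.cumsum(row), u, side="right"))
        s = min(s, 2)

    hyp = Hypnogram(labels=labels, epoch_len_s=EPOCH_LEN_S, start_zt=start_zt,
                    light_period_h=light_period_h)
    order = np.argsort(onsets)
    events = make_events(np.asarray(onsets)[order], np.asarray(offsets)[order],
                         channel="EEG_frontal",
                         state=np.asarray(ev_states, dtype=object)[order] if onsets else "",
                         provenance="ground_truth", start_zt=start_zt)
    if len(events):
        events["state"] = np.asarray(ev_states, dtype=object)[order]
    return hyp, events


# ---------------------------------------------------------------------------
# signal synthesis

#: Per-state EEG gains in microvolts RMS for the three background components
#: (slow: 0.5-3 Hz, broad: 0.5-45 Hz flat, theta: 5-9 Hz).
EEG_GAINS = {
    "WAKE": {"slow": 3.0, "broad": 13.0, "theta": 4.0},
    "SWS": {"slow": 45.0, "broad": 20.0, "theta": 5.0},
    "REM": {"slow": 3.0, "broad": 8.0, "theta": 10.0},
}

#: Per-state EMG tone in microvolts RMS (10-45 Hz noise).
EMG_GAINS = {"WAKE": 30.0, "SWS": 8.0, "REM": 4.0}

_COMPONENT_BANDS = {"slow": (0.5, 3.0), "broad": (0.5, 45.0), "theta": (5.0, 9.0)}


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz via FFT masking."""
    hi = min(hi, 0.95 * fs / 2)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _theta_oscillation(rng: np.random.Generator, n: int, fs: float,
                       f_center: float = 7.0, f_jitter: float = 0.6,
                       jitter_tau_s: float = 2.0) -> np.ndarray:
    """Unit-RMS sustained theta rhythm with slowly wandering frequency.

    Hippocampal theta is a continuous oscillation, not band-limited noise:
    its envelope is nearly constant while its instantaneous frequency
    wanders.  Modeled as ``sin(phi(t))`` with ``dphi/dt`` driven by an
    Ornstein-Uhlenbeck process around ``f_center``.
    """
    from scipy.signal import lfilter

    dt = 1.0 / fs
    alpha = np.exp(-dt / jitter_tau_s)
    innov = rng.standard_normal(n) * np.sqrt(1 - alpha**2)
    z = lfilter([1.0], [1.0, -alpha], innov)  # AR(1), unit stationary variance
    f_inst = f_center + f_jitter * z
    phase = 2 * np.pi * np.cumsum(f_inst) * dt + rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.sin(phase)


def _smooth_gains(gains_per_epoch: np.ndarray, ep_samples: int, n: int, fs: float) -> np.ndarray:
    g = np.repeat(gains_per_epoch, ep_samples)[:n]
    ramp = max(int(round(0.5 * fs)), 1)
    return ndimage.uniform_filter1d(g, ramp, mode="nearest")


def simulate_recording(profile: StrainProfile,
                       hyp_model: HypnogramModel | None = None,
                       waveform: SWDWaveformSpec | None = None,
                       duration_h: float = 24.0,
                       fs: float = 100.0,
                       seed: int = 0,
                       start_zt: float = 0.0,
                       light_period_h: float = 12.0,
                       mains_hz: float | None = None,
                       mains_amplitude_uv: float = 2.0):
    """Full co-simulation: returns ``(SignalRecording, Hypnogram, EventTable)``.

    ``mains_hz`` optionally injects a mains sinusoid so the notch stage can
    be exercised; by default no mains interference is simulated.
    """
    if fs < 100:
        raise ValidationError("simulation sampling rate must be >= 100 Hz")
    waveform = waveform or SWDWaveformSpec()
    hyp, events = simulate_ground_truth(profile, hyp_model, waveform, duration_h,
                                        seed, start_zt, light_period_h)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEE6]))

    n = int(round(duration_h * 3600 * fs))
    ep_samples = int(round(EPOCH_LEN_S * fs))

    eeg = np.zeros(n)
    for comp, (lo, hi) in _COMPONENT_BANDS.items():
        gains = np.array([EEG_GAINS[s][comp] for s in hyp.labels])
        g = _smooth_gains(gains, ep_samples, n, fs)
        if comp == "theta":
            eeg += g * _theta_oscillation(rng, n, fs)
        else:
            eeg += g * _band_noise(rng, n, fs, lo, hi)

    emg_gain = _smooth_gains(np.array([EMG_GAINS[s] for s in hyp.labels]),
                                  ep_samples, n, fs)
    emg = emg_gain * _band_noise(rng, n, fs, 10.0, 45.0)

    if mains_hz is not None:
        t = np.arange(n) / fs
        mains = mains_amplitude_uv * np.sin(2 * np.pi * mains_hz * t)
        eeg += mains
        emg += mains

    # inject discharges scaled to the local background RMS
    for onset, offset in zip(events["onset_s"], events["offset_s"]):
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        i1 = min(i1, n)
        if i1 - i0 < 2:
            continue
        seg_rms = np.sqrt(np.mean(eeg[i0:i1] ** 2))
        w = waveform.waveform((i1 - i0) / fs, fs)[: i1 - i0]
        eeg[i0:i1] += waveform.amplitude_factor * seg_rms * w

    rec = SignalRecording(
        channels=[Channel("EEG_frontal", "EEG_frontal", eeg),
                  Channel("EMG_nuchal", "EMG", emg)],
        fs=fs, start_zt=start_zt, light_period_h=light_period_h)
    return rec, hyp, events


# ---------------------------------------------------------------------------
# strain profiles

def _profile_dir() -> Path:
    return Path(str(importlib.resources.files("somnispike") / "profiles"))


def list_profiles() -> list[str]:
    return sorted(p.stem for p in _profile_dir().glob("*.yaml"))


def get_profile(name_or_path: str) -> StrainProfile:
    """Load a strain profile by shipped name (e.g. ``jax_like``) or YAML path."""
    path = Path(name_or_path)
    if not path.exists():
        path = _profile_dir() / f"{name_or_path}.yaml"
    if not path.exists():
        raise ProfileError(
            f"unknown profile {name_or_path!r}; known profiles: {list_profiles()}")
    data = yaml.safe_load(path.read_text())
    return StrainProfile(
        name=data["name"],
        daily_event_mean=float(data["daily_event_mean"]),
        state_rates={k: float(v) for k, v in data["state_rates"].items()},
        circadian_beta=float(data.get("circadian_beta", 1.24)),
        acrophase_h=float(data.get("acrophase_h", 12.0)),
        awakening_hazard=float(data.get("awakening_hazard", 3.0)),
    )


def export_fixture(seed: int, profile: StrainProfile | str, out_dir: str | Path,
                   duration_h: float = 24.0, fs: float = 100.0) -> dict[str, Path]:
    """Write the (EDF, hypnogram CSV, events CSV) triad for one simulation.

    Deterministic given ``(seed, profile)``: the same call produces
    byte-identical CSVs.
    """
    from . import io_formats

    if isinstance(profile, str):
        profile = get_profile(profile)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, hyp, events = simulate_recording(profile, duration_h=duration_h, fs=fs, seed=seed)
    paths = {
        "edf": out_dir / f"{profile.name}_seed{seed}.edf",
        "hypnogram": out_dir / f"{profile.name}_seed{seed}_hypnogram.csv",
        "events": out_dir / f"{profile.name}_seed{seed}_events.csv",
    }
    io_formats.write_edf(rec, paths["edf"])
    io_formats.write_hypnogram(hyp, paths["hypnogram"])
    io_formats.write_events(events, paths["events"])
    return paths
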