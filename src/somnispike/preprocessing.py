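"""Acquisition-chain filtering and artifact-epoch tagging.

The filter bank mirrors a typical rodent EEG/EMG acquisition chain: EEG
band-passed 0.3-70 Hz, EMG high-passed at 10 Hz, optional 50-Hz mains notch
on both.  Filters are applied zero-phase (forward-backward) so that event
boundary timing downstream carries no group delay; the trade-off relative
to the causal analog chain is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .types import ARTIFACT, Channel, Hypnogram, SignalRecording, ValidationError


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Filter corner frequencies in Hz.  ``notch_hz=None`` disables the notch
    (synthetic recordings carry no mains interference by default)."""

    eeg_hp_hz: float = 0.3
    eeg_lp_hz: float = 70.0
    emg_hp_hz: float = 10.0
    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.eeg_hp_hz >= self.eeg_lp_hz:
            raise ConfigurationError("EEG high-pass corner must lie below the low-pass corner")
        if self.notch_hz is not None and not (self.eeg_hp_hz < self.notch_hz < self.eeg_lp_hz):
            raise ConfigurationError("notch frequency must lie inside the EEG pass-band")


def _zero_phase_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x)


def apply_acquisition_filters(rec: SignalRecording, spec: FilterSpec = FilterSpec()) -> SignalRecording:
    """Return a filtered copy of ``rec`` (per-channel filtering by role)."""
    if rec.fs <= 2 * spec.eeg_lp_hz:
        raise ConfigurationError(
            f"sampling rate {rec.fs} Hz too low for a {spec.eeg_lp_hz} Hz low-pass")
    nyq = rec.fs / 2.0
    sos_eeg = signal.butter(spec.order, [spec.eeg_hp_hz / nyq, spec.eeg_lp_hz / nyq],
                            btype="bandpass", output="sos")
    sos_emg = signal.butter(spec.order, spec.emg_hp_hz / nyq, btype="highpass", output="sos")
    if spec.notch_hz is not None:
        b_n, a_n = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)

    out = []
    for c in rec.channels:
        x = c.data
        if c.role == "EMG":
            y = _zero_phase_sos(sos_emg, x)
        else:
            y = _zero_phase_sos(sos_eeg, x)
        if spec.notch_hz is not None:
            y = signal.filtfilt(b_n, a_n, y)
        out.append(Channel(name=c.name, role=c.role, data=y))
    return SignalRecording(channels=out, fs=rec.fs, start_zt=rec.start_zt,
                           light_period_h=rec.light_period_h)


@dataclass(frozen=True)
class ArtifactParams:
    """Amplitude rule for artifact epochs: samples beyond ``mad_factor`` times
    the recording-wide MAD for at least ``min_duration_s`` cumulative within
    an epoch mark it ARTIFACT.  A stand-in for manual tagging; thresholds are
    deliberately conservative so clean epochs are never excluded."""

    mad_factor: float = 10.0
    min_duration_s: float = 0.5
    clip_limit_uv: float | None = None


def tag_artifacts(rec: SignalRecording, hyp: Hypnogram,
                  params: ArtifactParams = ArtifactParams()) -> Hypnogram:
    """Relabel epochs with excessive EEG amplitude (or clipping) as ARTIFACT.

    The original labels are retained in ``Hypnogram.shadow``.  Epochs already
    marked ARTIFACT stay ARTIFACT.
    """
    x = rec.eeg().data
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    thr = params.mad_factor * mad if mad > 0 else np.inf

    n_ep = min(hyp.n_epochs, int(rec.duration_s // hyp.epoch_len_s))
    ep_len = int(round(hyp.epoch_len_s * rec.fs))
    labels = hyp.labels.copy()
    min_samples = params.min_duration_s * rec.fs
    for e in range(n_ep):
        seg = x[e * ep_len : (e + 1) * ep_len]
        bad = np.abs(seg - med) > thr
        if params.clip_limit_uv is not None:
            bad |= np.abs(seg) >= params.clip_limit_uv
        if bad.sum() >= min_samples:
            labels[e] = ARTIFACT
    shadow = hyp.shadow if hyp.shadow is not None else hyp.labels.copy()
    return Hypnogram(labels=labels, epoch_len_s=hyp.epoch_len_s, start_zt=hyp.start_zt,
                     light_period_h=hyp.light_period_h, shadow=shadow)
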