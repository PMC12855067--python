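"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* All on-disk and in-memory times are **seconds from recording start**;
  Zeitgeber time (ZT, hours since lights-on) is always derived from
  ``start_zt`` and never stored as a primary coordinate.
* Event intervals are half-open ``[onset_s, offset_s)``.
* Scoring epoch ``e`` covers ``[e * epoch_len_s, (e + 1) * epoch_len_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Vigilance-state alphabet used throughout.
STATES = ("WAKE", "SWS", "REM")
ARTIFACT = "ARTIFACT"
ALL_LABELS = STATES + (ARTIFACT,)

#: Channel roles the pipeline understands.
ROLES = ("EEG_frontal", "EEG_parietal", "EMG")

EVENT_COLUMNS = ["onset_s", "offset_s", "channel", "state", "onset_zt_h", "provenance"]
PROVENANCES = ("detected", "ground_truth", "curated")


class ValidationError(ValueError):
    """Raised when a container violates one of its documented invariants."""


class RoleMappingError(ValidationError):
    """Raised when channel labels cannot be mapped to unambiguous roles."""


class MissingChannelError(ValidationError):
    """Raised when an operation requires a channel role that is absent."""


@dataclass
class Channel:
    """One recorded trace: ``data`` holds samples in microvolts."""

    name: str
    role: str
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown channel role {self.role!r}; expected one of {ROLES}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValidationError("channel data must be a 1-D array")


@dataclass
class SignalRecording:
    """Multichannel EEG/EMG time series with a light-cycle anchor.

    Parameters
    ----------
    channels
        Traces in microvolts; all must share the same length.
    fs
        Sampling rate in Hz.
    start_zt
        Zeitgeber time (hours since lights-on) of sample 0, in ``[0, 24)``.
    light_period_h
        Duration of the lights-on block; 12 h for a 12:12 cycle.
    """

    channels: list[Channel]
    fs: float
    start_zt: float = 0.0
    light_period_h: float = 12.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if not self.channels:
            raise ValidationError("recording must contain at least one channel")
        n = len(self.channels[0].data)
        if any(len(c.data) != n for c in self.channels):
            raise ValidationError("all channels must have the same number of samples")
        if not 0 <= self.start_zt < 24:
            raise ValidationError("start_zt must lie in [0, 24)")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def zt_at(self, seconds: float | np.ndarray) -> float | np.ndarray:
        """ZT (hours) of a time point given in seconds from recording start."""
        return (self.start_zt + np.asarray(seconds) / 3600.0) % 24.0

    def is_lights_on(self, seconds: float | np.ndarray) -> bool | np.ndarray:
        return self.zt_at(seconds) < self.light_period_h

    def get(self, role: str) -> Channel:
        """Return the first channel with the requested role."""
        for c in self.channels:
            if c.role == role:
                return c
        raise MissingChannelError(f"recording has no channel with role {role!r}")

    def eeg(self) -> Channel:
        """Preferred EEG trace: frontal if present, else parietal."""
        for role in ("EEG_frontal", "EEG_parietal"):
            for c in self.channels:
                if c.role == role:
                    return c
        raise MissingChannelError("recording has no EEG channel")

    def emg(self) -> Channel:
        return self.get("EMG")


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels aligned to a recording.

    ``shadow`` optionally retains the pre-artifact-tagging labels so that
    artifact exclusion is auditable and reversible.
    """

    labels: np.ndarray
    epoch_len_s: float = 10.0
    start_zt: float = 0.0
    light_period_h: float = 12.0
    shadow: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U8")
        bad = set(np.unique(self.labels)) - set(ALL_LABELS)
        if self.labels.size and bad:
            raise ValidationError(f"unknown state labels {sorted(bad)}; alphabet is {ALL_LABELS}")
        if self.epoch_len_s <= 0:
            raise ValidationError("epoch length must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def epoch_start_s(self, e: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(e) * self.epoch_len_s

    def epoch_zt(self, e: int | np.ndarray) -> float | np.ndarray:
        """ZT (hours) of the start of epoch ``e``."""
        return (self.start_zt + np.asarray(e) * self.epoch_len_s / 3600.0) % 24.0

    def epoch_of(self, t_s: float | np.ndarray):
        """Index of the epoch containing time ``t_s`` (half-open epochs)."""
        return np.floor(np.asarray(t_s) / self.epoch_len_s).astype(int)

    def artifact_free(self) -> np.ndarray:
        return self.labels != ARTIFACT

    def hours_in_state(self, state: str) -> float:
        return float(np.sum(self.labels == state)) * self.epoch_len_s / 3600.0


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        EVENT_COLUMNS, [float, float, str, str, float, str])})


def make_events(onsets_s, offsets_s, channel="EEG_frontal", state="", zt=None,
                provenance="detected", start_zt: float = 0.0) -> pd.DataFrame:
    """Build an event table from parallel arrays of onsets and offsets."""
    onsets = np.asarray(onsets_s, dtype=float)
    offsets = np.asarray(offsets_s, dtype=float)
    if zt is None:
        zt = (start_zt + onsets / 3600.0) % 24.0
    df = pd.DataFrame({
        "onset_s": onsets,
        "offset_s": offsets,
        "channel": channel,
        "state": state,
        "onset_zt_h": zt,
        "provenance": provenance,
    })
    return validate_events(df)


def validate_events(df: pd.DataFrame, check_overlap: bool = True) -> pd.DataFrame:
    """Check event-table invariants and return the table sorted by onset.

    Raises :class:`ValidationError` on a non-positive duration or, when
    ``check_overlap`` is true, on same-channel overlapping intervals
    (ground-truth and detected tables must be non-overlapping after merge).
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"event table missing columns {missing}")
    if len(df) == 0:
        return df.reset_index(drop=True)
    if (df["onset_s"] >= df["offset_s"]).any():
        bad = df.index[df["onset_s"] >= df["offset_s"]].tolist()
        raise ValidationError(f"events with onset >= offset at rows {bad}")
    df = df.sort_values("onset_s", kind="mergesort").reset_index(drop=True)
    if check_overlap:
        for ch, grp in df.groupby("channel"):
            if (grp["onset_s"].to_numpy()[1:] < grp["offset_s"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping events on channel {ch!r}")
    return df
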