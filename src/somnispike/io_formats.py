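"""On-disk contracts: EDF signals, CSV hypnograms and event tables.

EDF was chosen as the signal container for interoperability with standard
polysomnography viewers.  EDF start times are wall-clock, so a JSON sidecar
(``<name>.zt.json``) carries the light-cycle anchor (``start_zt``,
``light_period_h``) and the exact sample count (EDF pads the final data
record).

Writing uses a self-contained EDF encoder (plain EDF, 16-bit, one-second
data records); reading goes through :func:`mne.io.read_raw_edf`, which also
serves as an independent check that the files we emit are valid EDF.
"""

from __future__ import annotations

import json
import math
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (ALL_LABELS, EVENT_COLUMNS, PROVENANCES, Channel, Hypnogram,
                    RoleMappingError, SignalRecording, ValidationError,
                    validate_events)

#: Documented mapping from channel-label substrings (lowercase) to roles.
#: Patterns are tried in order; the first hit wins.
ROLE_PATTERNS = [
    ("emg", "EMG"),
    ("muscle", "EMG"),
    ("nuchal", "EMG"),
    ("front", "EEG_frontal"),
    ("pariet", "EEG_parietal"),
    ("eeg", "EEG_frontal"),
]

HYPNOGRAM_HEADER = ["epoch_index", "zt_start_h", "state"]


def infer_role(label: str) -> str | None:
    low = label.lower()
    for pat, role in ROLE_PATTERNS:
        if pat in low:
            return role
    return None


def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # shorten numeric fields rather than corrupt the header
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: SignalRecording, path: str | Path) -> Path:
    """Write a recording as plain EDF plus a ``.zt.json`` sidecar.

    The physical range per channel is chosen symmetric around zero and just
    covering the signal, so quantization error is bounded by
    ``physical_range / 2**15`` per sample.
    """
    path = Path(path)
    if not rec.channels:
        raise ValidationError("cannot write an EDF with no channels")
    for c in rec.channels:
        if not np.all(np.isfinite(c.data)):
            raise ValidationError(f"channel {c.name!r} contains non-finite samples")
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs))

    n_records = max(1, math.ceil(rec.n_samples / fs))
    ns = len(rec.channels)

    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field("X X X X", 80)
    header += _ascii_field("Startdate X X X X", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (ns + 1), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)          # record duration: 1 s
    header += _ascii_field(ns, 4)

    phys_ranges = []
    for c in rec.channels:
        amax = float(np.max(np.abs(c.data))) if c.data.size else 0.0
        phys_ranges.append(max(amax * 1.0001, 1e-3))

    def per_signal(fmt, width):
        return b"".join(_ascii_field(fmt(c, r), width) for c, r in zip(rec.channels, phys_ranges))

    header += per_signal(lambda c, r: c.name[:16], 16)
    header += per_signal(lambda c, r: "", 80)
    header += per_signal(lambda c, r: "uV", 8)
    header += per_signal(lambda c, r: f"{-r:.6g}"[:8], 8)
    header += per_signal(lambda c, r: f"{r:.6g}"[:8], 8)
    header += per_signal(lambda c, r: -32768, 8)
    header += per_signal(lambda c, r: 32767, 8)
    header += per_signal(lambda c, r: "", 80)
    header += per_signal(lambda c, r: fs, 8)
    header += per_signal(lambda c, r: "", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        pad_len = n_records * fs
        digitized = []
        for c, r in zip(rec.channels, phys_ranges):
            x = np.zeros(pad_len)
            x[: rec.n_samples] = c.data
            d = np.clip(np.round(x / r * 32767), -32768, 32767).astype("<i2")
            digitized.append(d)
        for rec_i in range(n_records):
            for d in digitized:
                fh.write(d[rec_i * fs : (rec_i + 1) * fs].tobytes())

    sidecar = {
        "start_zt": rec.start_zt,
        "light_period_h": rec.light_period_h,
        "n_samples": rec.n_samples,
        "roles": {c.name: c.role for c in rec.channels},
    }
    path.with_suffix(path.suffix + ".zt.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_edf(path: str | Path) -> SignalRecording:
    """Read an EDF/EDF+ file into a :class:`SignalRecording`.

    Channel roles come from the sidecar when present, otherwise from the
    documented label-substring mapping (:data:`ROLE_PATTERNS`).  At least one
    EEG and one EMG channel must be identifiable.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = path.with_suffix(path.suffix + ".zt.json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise OSError(f"failed to read EDF {path}: {exc}") from exc

    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValidationError("channels with inconsistent sampling rates")
    fs = float(raw.info["sfreq"])

    roles_from_sidecar = sidecar.get("roles", {})
    channels = []
    for name in raw.ch_names:
        role = roles_from_sidecar.get(name) or infer_role(name)
        if role is None:
            raise RoleMappingError(
                f"cannot map channel label {name!r} to a role; known patterns: "
                f"{[p for p, _ in ROLE_PATTERNS]}")
        data = raw.get_data(picks=[name])[0] * 1e6  # volts -> microvolts
        channels.append(Channel(name=name, role=role, data=data))

    roles = {c.role for c in channels}
    if "EMG" not in roles:
        raise RoleMappingError("no channel mapped to EMG")
    if not roles & {"EEG_frontal", "EEG_parietal"}:
        raise RoleMappingError("no channel mapped to an EEG role")

    n = sidecar.get("n_samples")
    if n is not None:
        for c in channels:
            c.data = c.data[:n]

    return SignalRecording(
        channels=channels,
        fs=fs,
        start_zt=float(sidecar.get("start_zt", 0.0)),
        light_period_h=float(sidecar.get("light_period_h", 12.0)),
    )


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "zt_start_h": np.round(hyp.epoch_zt(np.arange(hyp.n_epochs)), 6),
        "state": hyp.labels,
    })
    df.to_csv(path, index=False)
    meta = {"epoch_len_s": hyp.epoch_len_s, "start_zt": hyp.start_zt,
            "light_period_h": hyp.light_period_h}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))
    return path


def read_hypnogram(path: str | Path, epoch_len_s: float | None = None) -> Hypnogram:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in HYPNOGRAM_HEADER if c not in df.columns]
    if missing:
        raise ValidationError(f"hypnogram CSV missing columns {missing}")
    bad = ~df["state"].isin(ALL_LABELS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"unknown state {df['state'][row]!r} at row {row}; alphabet is {ALL_LABELS}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if epoch_len_s is None:
        epoch_len_s = float(meta.get("epoch_len_s", 10.0))
    if len(df) == 0:
        warnings.warn(f"hypnogram {path} has zero epochs")
        start_zt = float(meta.get("start_zt", 0.0))
    else:
        start_zt = float(df["zt_start_h"].iloc[0])
    return Hypnogram(labels=df["state"].to_numpy(dtype="<U8"),
                     epoch_len_s=epoch_len_s, start_zt=start_zt,
                     light_period_h=float(meta.get("light_period_h", 12.0)))


def write_events(df: pd.DataFrame, path: str | Path) -> Path:
    df = validate_events(df, check_overlap=False)
    df.to_csv(path, index=False)
    return Path(path)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    bad = ~df["provenance"].isin(PROVENANCES)
    if len(df) and bad.any():
        raise ValidationError(f"unknown provenance values {sorted(set(df['provenance'][bad]))}")
    check_overlap = len(df) > 0 and (df["provenance"] == "detected").all()
    return validate_events(df, check_overlap=check_overlap)
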