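"""Rule-based vigilance-state scoring from EEG band power and EMG tone.

A transparent surrogate for visual staging: each 10-s epoch is classified
WAKE / SWS / REM from three features — EMG RMS, EEG delta (0.5-4 Hz)
fraction of total (0.5-30 Hz) power, and the theta/delta (5-9 / 0.5-4 Hz)
power ratio.  Thresholds can be given explicitly or calibrated per
recording ("auto").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import ARTIFACT, Hypnogram, MissingChannelError, SignalRecording, ValidationError

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (5.0, 9.0)
TOTAL_BAND = (0.5, 30.0)

#: Welch settings shared with the event-spectral stage: 2-s Hann window,
#: 0.5-s overlap.
WELCH_WINDOW_S = 2.0
WELCH_OVERLAP_S = 0.5


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    sel = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(pxx[..., sel], f[sel], axis=-1)


def extract_features(rec: SignalRecording, epoch_len_s: float = 10.0) -> pd.DataFrame:
    """Per-epoch features from the (already filtered) recording.

    Returns a DataFrame with columns ``delta_power``, ``theta_power``,
    ``total_power``, ``delta_fraction``, ``theta_delta_ratio`` (``inf``
    sentinel when delta power is zero) and ``emg_rms``.
    """
    if rec.duration_s < epoch_len_s:
        raise ValidationError("recording shorter than one epoch")
    eeg = rec.eeg().data
    emg = rec.emg().data
    ep = int(round(epoch_len_s * rec.fs))
    n_ep = len(eeg) // ep

    eeg_m = eeg[: n_ep * ep].reshape(n_ep, ep)
    emg_m = emg[: n_ep * ep].reshape(n_ep, ep)

    nperseg = min(int(round(WELCH_WINDOW_S * rec.fs)), ep)
    noverlap = int(round(WELCH_OVERLAP_S * rec.fs)) if nperseg < ep else 0
    f, pxx = signal.welch(eeg_m, fs=rec.fs, window="hann", nperseg=nperseg,
                          noverlap=noverlap, axis=-1)

    delta = _band_power(f, pxx, DELTA_BAND)
    theta = _band_power(f, pxx, THETA_BAND)
    total = _band_power(f, pxx, TOTAL_BAND)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, delta / total, 0.0)
        ratio = np.where(delta > 0, theta / delta, np.inf)
    return pd.DataFrame({
        "delta_power": delta,
        "theta_power": theta,
        "total_power": total,
        "delta_fraction": frac,
        "theta_delta_ratio": ratio,
        "emg_rms": np.sqrt(np.mean(emg_m**2, axis=1)),
    })


@dataclass(frozen=True)
class ScoringThresholds:
    emg_rms_uv: float
    delta_fraction: float
    theta_delta_ratio: float = 2.0


#: Fallback used when the EMG log-RMS distribution is not clearly bimodal.
FALLBACK_THRESHOLDS = ScoringThresholds(emg_rms_uv=15.0, delta_fraction=0.45,
                                        theta_delta_ratio=2.0)


def auto_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Quantile calibration per recording.

    EMG threshold: midpoint (in log space) between the two centers of a
    2-class 1-D k-means on log EMG RMS; if the two clusters are not clearly
    separated the distribution is treated as unimodal and fixed fallback
    thresholds are used (with a warning).  Delta threshold: 60th percentile
    of the delta fraction among sleep-candidate (low-EMG) epochs.
    """
    from sklearn.cluster import KMeans

    log_rms = np.log(features["emg_rms"].to_numpy() + 1e-12).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(log_rms)
    c = np.sort(km.cluster_centers_.ravel())
    within = np.sqrt(km.inertia_ / len(log_rms))
    if (c[1] - c[0]) < 2.0 * within or (c[1] - c[0]) < 0.2:
        warnings.warn("EMG log-RMS distribution looks unimodal; "
                      "falling back to fixed scoring thresholds")
        return FALLBACK_THRESHOLDS
    emg_thr = float(np.exp(c.mean()))
    sleepers = features.loc[features["emg_rms"] < emg_thr, "delta_fraction"]
    if len(sleepers) == 0:
        warnings.warn("no sleep-candidate epochs; falling back to fixed thresholds")
        return FALLBACK_THRESHOLDS
    delta_thr = float(np.quantile(sleepers, 0.60))
    return ScoringThresholds(emg_rms_uv=emg_thr, delta_fraction=delta_thr)


def score(features: pd.DataFrame,
          thresholds: ScoringThresholds | str = "auto",
          artifact_mask: np.ndarray | None = None,
          start_zt: float = 0.0, epoch_len_s: float = 10.0,
          light_period_h: float = 12.0) -> Hypnogram:
    """Classify each epoch.

    Rule order: WAKE if EMG RMS above threshold; else SWS if the delta
    fraction reaches its threshold; else REM if theta/delta reaches its
    threshold; else SWS.  Epochs flagged in ``artifact_mask`` are passed
    through as ARTIFACT.
    """
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValidationError("thresholds must be a ScoringThresholds or 'auto'")
        thresholds = auto_thresholds(features)

    labels = np.empty(len(features), dtype="<U8")
    wake = features["emg_rms"].to_numpy() > thresholds.emg_rms_uv
    sws = features["delta_fraction"].to_numpy() >= thresholds.delta_fraction
    rem = features["theta_delta_ratio"].to_numpy() >= thresholds.theta_delta_ratio
    labels[:] = "SWS"
    labels[~wake & ~sws & rem] = "REM"
    labels[wake] = "WAKE"
    if artifact_mask is not None:
        labels[np.asarray(artifact_mask, bool)] = ARTIFACT
    return Hypnogram(labels=labels, epoch_len_s=epoch_len_s, start_zt=start_zt,
                     light_period_h=light_period_h)


def score_recording(rec: SignalRecording,
                    thresholds: ScoringThresholds | str = "auto",
                    artifact_mask: np.ndarray | None = None,
                    epoch_len_s: float = 10.0) -> Hypnogram:
    """Convenience wrapper: features + scoring in one call.

    Raises :class:`MissingChannelError` if the recording has no EMG channel
    — the WAKE/REM distinction is undefined without muscle tone, so the
    scorer refuses rather than guessing.
    """
    rec.emg()  # fail fast with a clear message
    feats = extract_features(rec, epoch_len_s)
    return score(feats, thresholds, artifact_mask, start_zt=rec.start_zt,
                 epoch_len_s=epoch_len_s, light_period_h=rec.light_period_h)


def evaluate_scoring(pred: Hypnogram, truth: Hypnogram) -> dict:
    """Epoch-level confusion summary: accuracy, Cohen's kappa and per-state
    precision/recall (ARTIFACT epochs in either hypnogram are excluded)."""
    from sklearn.metrics import cohen_kappa_score, confusion_matrix

    if pred.n_epochs != truth.n_epochs:
        raise ValidationError("hypnograms have different epoch counts")
    keep = (pred.labels != ARTIFACT) & (truth.labels != ARTIFACT)
    y_pred, y_true = pred.labels[keep], truth.labels[keep]
    states = ["WAKE", "SWS", "REM"]
    cm = confusion_matrix(y_true, y_pred, labels=states)
    per_state = {}
    for i, s in enumerate(states):
        tp = cm[i, i]
        per_state[s] = {
            "precision": tp / cm[:, i].sum() if cm[:, i].sum() else np.nan,
            "recall": tp / cm[i].sum() if cm[i].sum() else np.nan,
        }
    n_agree = int(np.sum(y_pred == y_true))
    kappa = (cohen_kappa_score(y_true, y_pred, labels=states)
             if len(set(y_true)) > 1 or len(set(y_pred)) > 1 else 1.0)
    return {
        "accuracy": n_agree / len(y_true) if len(y_true) else np.nan,
        "kappa": float(kappa),
        "confusion": cm,
        "states": states,
        "per_state": per_state,
        "n_epochs": int(len(y_true)),
    }
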