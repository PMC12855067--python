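"""Two-stage spike-and-wave discharge detection.

The permissive first pass marks contiguous stretches where the analytic
envelope of the band-passed (4-20 Hz) EEG reaches ``threshold_factor``
(1.5) times a rolling background level; nearby stretches are merged and a
candidate is accepted only if it contains at least ``min_cycles`` (4)
supra-threshold oscillation peaks whose successive intervals fall inside
the cycle-period bounds of the detection band.  Boundaries are extended to
the nearest zero crossings beyond the first and last counted peak.  A
review-export stage stands in for human curation.

The background level is the rolling median of the smoothed envelope over a
60-s window, computed from artifact-free signal only, so the discharges
themselves cannot inflate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .types import (ARTIFACT, Hypnogram, SignalRecording, ValidationError,
                    empty_events, make_events, validate_events)


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    band_hz: tuple[float, float] = (4.0, 20.0)
    background_window_s: float = 60.0
    threshold_factor: float = 1.5
    min_cycles: int = 4
    #: admissible interval between successive cycle peaks: the period range
    #: of the detection band.
    cycle_period_bounds_s: tuple[float, float] = (1.0 / 20.0, 1.0 / 4.0)
    merge_gap_s: float = 0.3
    #: detection band-pass order (applied forward-backward); steep skirts
    #: keep slow-wave (delta) power out of the detection band.
    filter_order: int = 8
    #: moving-average smoothing of the analytic envelope before thresholding.
    #: An SWD sustains its envelope for its whole duration, while background
    #: envelope excursions decorrelate within a fraction of a second, so
    #: averaging over ~2 s separates the two populations; cycle counting
    #: compensates for the resulting edge shrinkage by widening its search
    #: window.  The 4-Hz band floor keeps slow-wave activity, whose envelope
    #: fluctuates too slowly to average out, off the detector entirely.
    envelope_smooth_s: float = 2.0
    #: resolution of the rolling background estimate.
    background_block_s: float = 1.0
    #: running-max guard on the block background: within this distance of a
    #: vigilance-state boundary the larger neighbouring background applies,
    #: so envelope bleed across scored-state edges is not read as an event.
    boundary_guard_s: float = 2.0
    background_floor_uv: float = 1e-6

    def __post_init__(self) -> None:
        if self.threshold_factor <= 1:
            raise ValidationError("threshold factor must exceed 1")
        if self.min_cycles < 1:
            raise ValidationError("min cycles must be >= 1")


def band_envelope(rec: SignalRecording, params: DetectionParams = DetectionParams()):
    """Band-passed EEG and its smoothed analytic (Hilbert) envelope."""
    x = rec.eeg().data
    nyq = rec.fs / 2.0
    sos = signal.butter(params.filter_order,
                        [params.band_hz[0] / nyq, params.band_hz[1] / nyq],
                        btype="bandpass", output="sos")
    xb = signal.sosfiltfilt(sos, x)
    n = len(xb)
    from scipy.fft import next_fast_len
    env = np.abs(signal.hilbert(xb, N=next_fast_len(n))[:n])
    k = max(int(round(params.envelope_smooth_s * rec.fs)), 1)
    if k > 1:
        from scipy.ndimage import uniform_filter1d
        env = uniform_filter1d(env, k, mode="nearest")
    return xb, env


def estimate_background(rec: SignalRecording, hyp: Hypnogram | None = None,
                        params: DetectionParams = DetectionParams(),
                        envelope: np.ndarray | None = None) -> np.ndarray:
    """Per-sample background level.

    Block medians (1-s blocks) of the smoothed envelope are taken, artifact
    blocks are dropped, and a rolling median over the background window
    (60 s worth of blocks) smooths the block series; the result is resampled
    to per-sample resolution and floored at ``background_floor_uv``.

    When a hypnogram is supplied the rolling median is computed over the
    nearest blocks of the *same vigilance state*: rodent EEG amplitude is
    strongly state-dependent, and a state-blind 60-s window would make every
    short high-amplitude sleep bout inside wakefulness look like a
    discharge.  "Background" is therefore read as 60 s of comparable
    (same-state, artifact-free) signal.
    """
    if envelope is None:
        _, envelope = band_envelope(rec, params)
    fs = rec.fs
    block = max(int(round(params.background_block_s * fs)), 1)
    n_blocks = len(envelope) // block
    if n_blocks == 0:
        raise DetectionError("recording shorter than one background block")
    bm = np.median(envelope[: n_blocks * block].reshape(n_blocks, block), axis=1)

    w = max(int(round(params.background_window_s / params.background_block_s)), 1)
    min_p = max(w // 6, 1)

    def _roll(series: pd.Series) -> pd.Series:
        return series.rolling(w, center=True, min_periods=min_p).median()

    if hyp is not None:
        t_block = (np.arange(n_blocks) + 0.5) * params.background_block_s
        ep = np.minimum((t_block // hyp.epoch_len_s).astype(int), hyp.n_epochs - 1)
        block_state = hyp.labels[ep]
        usable = block_state != ARTIFACT
        if not usable.any():
            raise DetectionError("no background available: every epoch is ARTIFACT")
        bg_blocks = np.full(n_blocks, np.nan)
        global_fill = _roll(pd.Series(np.where(usable, bm, np.nan))).ffill().bfill()
        for state in np.unique(block_state[usable]):
            idx = np.flatnonzero(usable & (block_state == state))
            if len(idx) >= min_p:
                compact = _roll(pd.Series(bm[idx])).ffill().bfill().to_numpy()
                bg_blocks[idx] = compact
            else:
                bg_blocks[idx] = global_fill.to_numpy()[idx]
        # artifact blocks inherit the global estimate (excluded downstream)
        bg_blocks = pd.Series(bg_blocks).fillna(global_fill).to_numpy()
        guard = int(round(params.boundary_guard_s / params.background_block_s))
        if guard > 0:
            from scipy.ndimage import maximum_filter1d
            # within a state the rolled background is nearly constant, so the
            # running max only acts across state boundaries
            bg_blocks = maximum_filter1d(bg_blocks, 2 * guard + 1, mode="nearest")
    else:
        bg_blocks = _roll(pd.Series(bm)).ffill().bfill().to_numpy()

    bg = np.repeat(bg_blocks, block)
    bg = np.concatenate([bg, np.full(len(envelope) - len(bg), bg_blocks[-1])])
    return np.maximum(bg, params.background_floor_uv)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _best_chain(peak_idx: np.ndarray, lo: int, hi: int) -> tuple[int, int, int]:
    """Longest run of successive peaks whose intervals lie in [lo, hi] samples.

    Returns (count, first_peak, last_peak); count is the number of peaks in
    the chain (1 if no admissible interval exists).
    """
    if len(peak_idx) == 0:
        return 0, -1, -1
    best = (1, peak_idx[0], peak_idx[0])
    start = 0
    for i in range(1, len(peak_idx) + 1):
        ok = (i < len(peak_idx)
              and lo <= peak_idx[i] - peak_idx[i - 1] <= hi)
        if not ok:
            count = i - start
            if count > best[0]:
                best = (count, peak_idx[start], peak_idx[i - 1])
            start = i
    return best


def detect_candidates(rec: SignalRecording,
                      background: np.ndarray | None = None,
                      params: DetectionParams = DetectionParams(),
                      hyp: Hypnogram | None = None) -> pd.DataFrame:
    """Run the permissive pass plus the cycle filter; returns an event table
    (provenance ``detected``) with ``n_cycles`` and ``peak_amplitude_ratio``
    columns appended."""
    xb, env = band_envelope(rec, params)
    if background is None:
        background = estimate_background(rec, hyp, params, envelope=env)
    if len(background) != len(env):
        raise ValidationError("background length does not match the recording")
    fs = rec.fs
    thr = params.threshold_factor * background

    runs = _runs(env >= thr)
    runs = _merge_runs(runs, int(round(params.merge_gap_s * fs)))

    lo = int(np.floor(params.cycle_period_bounds_s[0] * fs))
    hi = int(np.ceil(params.cycle_period_bounds_s[1] * fs))

    # positive oscillation peaks above threshold, computed once globally;
    # maxima closer than the shortest admissible cycle period are one cycle
    peaks, _ = signal.find_peaks(xb, distance=max(lo, 1))
    supra = peaks[xb[peaks] >= thr[peaks]]

    onsets, offsets, cycles, ratios = [], [], [], []
    n = len(xb)
    for s, e in runs:
        in_run = supra[(supra >= s) & (supra < e)]
        count, first, last = _best_chain(in_run, lo, hi)
        if count < params.min_cycles:
            continue
        # boundary rule: nearest zero crossing beyond the first/last peak
        i0 = first
        while i0 > 0 and xb[i0 - 1] > 0:
            i0 -= 1
        i1 = last
        while i1 < n - 1 and xb[i1 + 1] > 0:
            i1 += 1
        i1 = min(i1 + 1, n)
        onsets.append(i0 / fs)
        offsets.append(i1 / fs)
        cycles.append(count)
        ratios.append(float(np.max(env[s:e] / background[s:e])))

    if not onsets:
        return empty_events().assign(n_cycles=pd.Series(dtype=int),
                                     peak_amplitude_ratio=pd.Series(dtype=float))
    order = np.argsort(onsets)
    onsets_a, offsets_a = np.asarray(onsets)[order], np.asarray(offsets)[order]
    df = pd.DataFrame({
        "onset_s": onsets_a,
        "offset_s": offsets_a,
        "channel": rec.eeg().name,
        "state": "",
        "onset_zt_h": (rec.start_zt + onsets_a / 3600.0) % 24.0,
        "provenance": "detected",
        "n_cycles": np.asarray(cycles)[order],
        "peak_amplitude_ratio": np.asarray(ratios)[order],
    })
    # boundary extension and window widening can make neighbours touch;
    # merge any residual overlap before validating
    df = _merge_overlapping(df)
    return df


def _merge_overlapping(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) < 2:
        return df
    rows = [df.iloc[0].copy()]
    for _, r in df.iloc[1:].iterrows():
        if r["onset_s"] < rows[-1]["offset_s"]:
            rows[-1]["offset_s"] = max(rows[-1]["offset_s"], r["offset_s"])
            rows[-1]["n_cycles"] = rows[-1]["n_cycles"] + r["n_cycles"]
            rows[-1]["peak_amplitude_ratio"] = max(rows[-1]["peak_amplitude_ratio"],
                                                   r["peak_amplitude_ratio"])
        else:
            rows.append(r.copy())
    return validate_events(pd.DataFrame(rows).reset_index(drop=True))


def evaluate_detection(detected: pd.DataFrame, truth: pd.DataFrame,
                       tolerance_s: float = 0.5) -> dict:
    """Match detected to ground-truth events and summarize performance.

    A pair matches if the interval overlap covers at least half of the
    shorter event or the onsets agree within ``tolerance_s``.  Matching is
    greedy in onset order; each event matches at most once.
    """
    det = detected.sort_values("onset_s").reset_index(drop=True)
    tru = truth.sort_values("onset_s").reset_index(drop=True)
    used = np.zeros(len(det), dtype=bool)
    onset_errors = []
    tp = 0
    for _, t in tru.iterrows():
        best_j, best_ov = -1, 0.0
        for j in range(len(det)):
            if used[j]:
                continue
            d = det.iloc[j]
            ov = min(t["offset_s"], d["offset_s"]) - max(t["onset_s"], d["onset_s"])
            shorter = min(t["offset_s"] - t["onset_s"], d["offset_s"] - d["onset_s"])
            if (ov >= 0.5 * shorter and ov > 0) or abs(d["onset_s"] - t["onset_s"]) <= tolerance_s:
                if ov > best_ov or best_j < 0:
                    best_j, best_ov = j, ov
        if best_j >= 0:
            used[best_j] = True
            tp += 1
            onset_errors.append(abs(det.iloc[best_j]["onset_s"] - t["onset_s"]))
    recall = tp / len(tru) if len(tru) else np.nan
    precision = tp / len(det) if len(det) else np.nan
    return {
        "n_truth": int(len(tru)),
        "n_detected": int(len(det)),
        "true_positives": int(tp),
        "recall": recall,
        "precision": precision,
        "onset_mae_s": float(np.mean(onset_errors)) if onset_errors else np.nan,
    }


def export_review(rec: SignalRecording, events: pd.DataFrame, out_dir: str | Path,
                  window_s: float = 5.0, plot: bool = True) -> Path:
    """Write a per-event audit bundle for (simulated) visual curation.

    One trace-snippet CSV (and optional PNG) per event plus a single
    ``review_template.csv`` with an editable ``decision`` column
    (``accept``/``reject``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(events) == 0:
        warnings.warn("no events to review; writing empty template")
    eeg = rec.eeg().data
    fs = rec.fs
    rows = []
    for i, ev in events.reset_index(drop=True).iterrows():
        c = 0.5 * (ev["onset_s"] + ev["offset_s"])
        i0 = max(int((c - window_s / 2) * fs), 0)
        i1 = min(int((c + window_s / 2) * fs), len(eeg))
        snip = pd.DataFrame({"t_s": np.arange(i0, i1) / fs, "eeg_uv": eeg[i0:i1]})
        snip.to_csv(out_dir / f"event_{i:04d}.csv", index=False)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(8, 2.5))
            ax.plot(snip["t_s"], snip["eeg_uv"], lw=0.5, color="k")
            ax.axvspan(ev["onset_s"], ev["offset_s"], alpha=0.2, color="tab:red")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("EEG (uV)")
            fig.savefig(out_dir / f"event_{i:04d}.png", dpi=100)
            plt.close(fig)
        rows.append({"event_index": i, "onset_s": ev["onset_s"],
                     "offset_s": ev["offset_s"], "decision": "accept"})
    pd.DataFrame(rows, columns=["event_index", "onset_s", "offset_s", "decision"]) \
        .to_csv(out_dir / "review_template.csv", index=False)
    return out_dir


def apply_review(events: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    """Filter an event table by a completed review template; the surviving
    events are relabeled with provenance ``curated``."""
    keep_idx = template.loc[template["decision"].str.lower() == "accept",
                            "event_index"].to_numpy()
    out = events.reset_index(drop=True).iloc[sorted(set(keep_idx))].copy()
    out["provenance"] = "curated"
    return out.reset_index(drop=True)
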