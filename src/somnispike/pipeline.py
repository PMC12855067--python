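"""End-to-end orchestration: simulate-or-load -> filter -> score -> detect ->
spectra -> architecture -> interaction -> circadian, per animal, plus cohort
aggregation and a human-readable report.

Every run writes its resolved configuration next to its outputs, and the
whole chain is deterministic given (config, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (circadian, event_spectral, io_formats, preprocessing,
               sleep_metrics, sleep_scoring, swd_detection, synthetic_data)
from .types import Hypnogram, SignalRecording, ValidationError

log = logging.getLogger("somnispike")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    profile: str = "jax_like"
    seeds: list[int] = field(default_factory=lambda: [1])
    duration_h: float = 24.0
    fs: float = 100.0
    epoch_len_s: float = 10.0
    out_dir: str = "somnispike_out"
    save_signals: bool = False
    mains_hz: float | None = None
    filter_overrides: dict = field(default_factory=dict)
    detection_overrides: dict = field(default_factory=dict)
    artifact_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
        return cls(**data)

    def resolved_filter_spec(self) -> preprocessing.FilterSpec:
        """Filter corners adapted to the simulation rate: the low-pass is
        capped below Nyquist, and the mains notch is enabled only when mains
        interference is actually simulated."""
        kw = dict(eeg_lp_hz=min(70.0, 0.4 * self.fs),
                  notch_hz=self.mains_hz)
        kw.update(self.filter_overrides)
        return preprocessing.FilterSpec(**kw)

    def resolved_detection_params(self) -> swd_detection.DetectionParams:
        return swd_detection.DetectionParams(**self.detection_overrides)

    def parameter_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analyze_recording(rec: SignalRecording, config: PipelineConfig | None = None,
                      truth_hyp: Hypnogram | None = None,
                      truth_events: pd.DataFrame | None = None,
                      boot_seed: int = 0) -> dict:
    """Run every analysis stage on one (filtered or raw) recording.

    Returns a dictionary with the scored hypnogram, detected events and all
    stage summaries; when ground truth is supplied, scoring and detection
    accuracy are evaluated against it.
    """
    config = config or PipelineConfig(fs=rec.fs)
    filt = preprocessing.apply_acquisition_filters(rec, config.resolved_filter_spec())

    feats = sleep_scoring.extract_features(filt, config.epoch_len_s)
    hyp = sleep_scoring.score(feats, "auto", start_zt=rec.start_zt,
                              epoch_len_s=config.epoch_len_s,
                              light_period_h=rec.light_period_h)
    hyp = preprocessing.tag_artifacts(
        filt, hyp, preprocessing.ArtifactParams(**config.artifact_overrides))
    if not hyp.artifact_free().any():
        raise ValidationError("no analyzable epochs: every epoch is ARTIFACT")

    params = config.resolved_detection_params()
    events = swd_detection.detect_candidates(filt, params=params, hyp=hyp)
    events, attribution = sleep_metrics.attribute_events(events, hyp)

    spectra = event_spectral.recording_event_spectra(filt, hyp, events)
    peaks1 = [s.peak1_hz for s in spectra if s.peak1_hz is not None]
    peaks2 = [s.peak2_hz for s in spectra if s.peak2_hz is not None]

    arch = sleep_metrics.summarize_architecture(hyp)
    interaction = sleep_metrics.conditional_transitions(events, hyp, seed=boot_seed)
    circ = circadian.circadian_summary(events, hyp)

    result = {
        "hypnogram": hyp,
        "events": events,
        "attribution": attribution,
        "architecture": arch,
        "interaction": interaction,
        "circadian": circ,
        "spectra": spectra,
        "n_events": int(len(events)),
        "mean_event_duration_s": (float((events["offset_s"] - events["onset_s"]).mean())
                                  if len(events) else np.nan),
        "mean_peak1_hz": float(np.mean(peaks1)) if peaks1 else np.nan,
        "mean_peak2_hz": float(np.mean(peaks2)) if peaks2 else np.nan,
    }
    if truth_hyp is not None:
        result["scoring_eval"] = sleep_scoring.evaluate_scoring(hyp, truth_hyp)
    if truth_events is not None:
        result["detection_eval"] = swd_detection.evaluate_detection(events, truth_events)
    return result


def run_animal(config: PipelineConfig, seed: int) -> dict:
    """Simulate one animal-day and analyze it."""
    profile = synthetic_data.get_profile(config.profile)
    rec, truth_hyp, truth_events = synthetic_data.simulate_recording(
        profile, duration_h=config.duration_h, fs=config.fs, seed=seed,
        mains_hz=config.mains_hz)
    res = analyze_recording(rec, config, truth_hyp, truth_events, boot_seed=seed)
    res["seed"] = seed
    res["recording"] = rec
    res["truth_hypnogram"] = truth_hyp
    res["truth_events"] = truth_events
    return res


def _summary_row(res: dict) -> dict:
    arch = res["architecture"]
    att = res["attribution"]
    inter = res["interaction"]
    cos = res["circadian"]["cosinor"]
    row = {
        "seed": res.get("seed"),
        "n_events": res["n_events"],
        "mean_event_duration_s": res["mean_event_duration_s"],
        "mean_peak1_hz": res["mean_peak1_hz"],
        "mean_peak2_hz": res["mean_peak2_hz"],
        "sws_fraction": arch.fractions["SWS"],
        "rem_fraction": arch.fractions["REM"],
        "wake_fraction": arch.fractions["WAKE"],
        "transitions_per_h": arch.transitions_per_h,
        "n_transitions": arch.n_transitions,
        "sws_event_share_pct": att["shares_pct"]["SWS"],
        "wake_event_share_pct": att["shares_pct"]["WAKE"],
        "rem_event_share_pct": att["shares_pct"]["REM"],
        "p_trans_given_swd": inter["p_transition_given_swd"],
        "p_trans_given_clean": inter["p_transition_given_clean"],
        "coupling_ratio": inter["ratio"],
        "cosinor_mesor": cos.mesor if cos else np.nan,
        "cosinor_amplitude": cos.amplitude if cos else np.nan,
        "cosinor_acrophase_h": cos.acrophase_h if cos else np.nan,
    }
    if "scoring_eval" in res:
        row["scoring_accuracy"] = res["scoring_eval"]["accuracy"]
        row["scoring_kappa"] = res["scoring_eval"]["kappa"]
    if "detection_eval" in res:
        row["detection_recall"] = res["detection_eval"]["recall"]
        row["detection_precision"] = res["detection_eval"]["precision"]
    return row


def run_all(config: PipelineConfig) -> dict:
    """Run the cohort defined by the config; returns the bundle and writes
    per-animal artifacts plus a cohort summary CSV under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    log.info("pipeline start: profile=%s seeds=%s param_hash=%s",
             config.profile, config.seeds, config.parameter_hash())

    rows, animals = [], {}
    for seed in config.seeds:
        try:
            res = run_animal(config, seed)
        except Exception as exc:
            raise RuntimeError(f"stage failure for seed {seed} "
                               f"(partial outputs in {out})") from exc
        adir = out / f"animal_seed{seed}"
        adir.mkdir(exist_ok=True)
        io_formats.write_hypnogram(res["hypnogram"], adir / "hypnogram.csv")
        io_formats.write_events(res["events"], adir / "events.csv")
        res["circadian"]["histogram"].to_csv(adir / "hourly_histogram.csv", index=False)
        if config.save_signals:
            io_formats.write_edf(res["recording"], adir / "recording.edf")
        row = _summary_row(res)
        rows.append(row)
        animals[seed] = res
        (adir / "summary.json").write_text(json.dumps(
            {k: v for k, v in row.items() if not isinstance(v, (pd.DataFrame,))},
            indent=1, default=float))

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "cohort_summary.csv", index=False)

    cohort = {"summary": summary, "animals": animals, "out_dir": out}
    if len(summary) >= 3 and summary["n_events"].std() > 0 \
            and summary["n_transitions"].std() > 0:
        corr = sleep_metrics.correlate_fragmentation(
            summary["n_transitions"], summary["n_events"])
        cohort["fragmentation_correlation"] = corr
        (out / "fragmentation_correlation.json").write_text(json.dumps(
            dataclasses.asdict(corr), indent=1, default=float))
    return cohort


def make_report(bundle: dict | str | Path, path: str | Path | None = None) -> Path:
    """Render the cohort bundle to a Markdown report with summary figures.

    Accepts the in-memory bundle from :func:`run_all` or its output
    directory.  Missing stages are flagged rather than fatal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(bundle, (str, Path)):
        out = Path(bundle)
        summary_path = out / "cohort_summary.csv"
        if not summary_path.exists():
            raise FileNotFoundError(f"no cohort summary in {out}")
        summary = pd.read_csv(summary_path)
        bundle = {"summary": summary, "out_dir": out}
    summary = bundle["summary"]
    if len(summary) == 0:
        raise ValidationError("empty bundle: nothing to report")
    out = Path(bundle["out_dir"])
    path = Path(path) if path else out / "report.md"

    lines = ["# Cohort report", "",
             f"Animals: {len(summary)}", "", "## Per-animal summary", "",
             summary.to_markdown(index=False), ""]

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(summary["seed"].astype(str), summary["n_events"], color="tab:blue")
    ax.set_xlabel("animal (seed)")
    ax.set_ylabel("detected events / 24 h")
    fig.tight_layout()
    fig.savefig(out / "events_per_animal.png", dpi=110)
    plt.close(fig)
    lines += ["![events per animal](events_per_animal.png)", ""]

    hist_files = sorted(out.glob("animal_seed*/hourly_histogram.csv"))
    if hist_files:
        hourly = sum(pd.read_csv(f)["count"].to_numpy() for f in hist_files) / len(hist_files)
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(np.arange(24), hourly, color="tab:orange")
        ax.axvspan(12, 24, color="k", alpha=0.12)
        ax.set_xlabel("ZT (h)")
        ax.set_ylabel("mean events / h")
        fig.tight_layout()
        fig.savefig(out / "hourly_mean.png", dpi=110)
        plt.close(fig)
        lines += ["![mean hourly event counts](hourly_mean.png)", ""]
    else:
        lines += ["_Circadian section unavailable (no hourly histograms found)._", ""]

    cols = {"coupling_ratio": "Mean post-SWD / clean transition ratio",
            "mean_peak1_hz": "Mean first spectral peak (Hz)",
            "mean_peak2_hz": "Mean second spectral peak (Hz)",
            "mean_event_duration_s": "Mean event duration (s)"}
    lines += ["## Cohort means", ""]
    for col, label in cols.items():
        if col in summary and summary[col].notna().any():
            lines.append(f"- {label}: {summary[col].mean():.3f}")
        else:
            lines.append(f"- {label}: unavailable")
    path.write_text("\n".join(lines) + "\n")
    return path
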