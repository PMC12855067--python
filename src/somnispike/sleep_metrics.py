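"""Sleep architecture, fragmentation and SWD-sleep interaction statistics.

Transitions are defined at epoch resolution (adjacent-label change among
artifact-free epochs).  ARTIFACT epochs break runs without creating
transitions: a WAKE-ARTIFACT-WAKE sequence contributes two WAKE bouts and
no transition, so artifact exclusion can never inflate fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ARTIFACT, Hypnogram, STATES, ValidationError

#: The six ordered state pairs used for transition breakdowns.
TRANSITION_PAIRS = [("WAKE", "SWS"), ("SWS", "WAKE"), ("SWS", "REM"),
                    ("REM", "WAKE"), ("REM", "SWS"), ("WAKE", "REM")]


@dataclass
class ArchitectureSummary:
    fractions: dict[str, float]
    bout_counts: dict[str, int]
    mean_bout_s: dict[str, float]
    n_transitions: int
    transitions_per_h: float
    pair_frequencies: dict[tuple[str, str], float]
    n_artifact_free_epochs: int
    n_segments: int


def _segments(labels: np.ndarray) -> list[np.ndarray]:
    """Maximal contiguous artifact-free stretches of the label sequence."""
    segs, cur = [], []
    for lab in labels:
        if lab == ARTIFACT:
            if cur:
                segs.append(np.array(cur))
                cur = []
        else:
            cur.append(lab)
    if cur:
        segs.append(np.array(cur))
    return segs


def summarize_architecture(hyp: Hypnogram) -> ArchitectureSummary:
    """Time in state, bouts, transition counts and pair frequencies."""
    usable = int(hyp.artifact_free().sum())
    if usable < 2:
        raise ValidationError("fewer than 2 artifact-free epochs; nothing to analyze")
    segs = _segments(hyp.labels)

    bout_counts = {s: 0 for s in STATES}
    bout_epochs = {s: 0 for s in STATES}
    pair_counts = {p: 0 for p in TRANSITION_PAIRS}
    n_trans = 0
    for seg in segs:
        change = np.flatnonzero(seg[1:] != seg[:-1])
        n_trans += len(change)
        for i in change:
            pair = (str(seg[i]), str(seg[i + 1]))
            if pair in pair_counts:
                pair_counts[pair] += 1
        starts = np.r_[0, change + 1]
        ends = np.r_[change + 1, len(seg)]
        for a, b in zip(starts, ends):
            s = str(seg[a])
            bout_counts[s] += 1
            bout_epochs[s] += b - a

    total_bouts = sum(bout_counts.values())
    assert n_trans == total_bouts - len(segs), "run-length identity violated"

    hours = usable * hyp.epoch_len_s / 3600.0
    fractions = {s: bout_epochs[s] / usable for s in STATES}
    mean_bout = {s: (bout_epochs[s] / bout_counts[s] * hyp.epoch_len_s
                     if bout_counts[s] else np.nan) for s in STATES}
    pair_freq = {p: (pair_counts[p] / n_trans if n_trans else np.nan)
                 for p in TRANSITION_PAIRS}
    return ArchitectureSummary(
        fractions=fractions, bout_counts=bout_counts, mean_bout_s=mean_bout,
        n_transitions=n_trans, transitions_per_h=n_trans / hours,
        pair_frequencies=pair_freq, n_artifact_free_epochs=usable,
        n_segments=len(segs))


def attribute_events(events: pd.DataFrame, hyp: Hypnogram) -> tuple[pd.DataFrame, dict]:
    """Label each event with its onset epoch's state and compute per-state rates.

    Events whose onset epoch is ARTIFACT are labeled ARTIFACT and excluded
    from state shares (counted separately).  Rates are events per hour spent
    in each state (artifact-free time only).
    """
    events = events.copy().reset_index(drop=True)
    if len(events):
        ep = hyp.epoch_of(events["onset_s"].to_numpy())
        if (ep < 0).any() or (ep >= hyp.n_epochs).any():
            raise ValidationError("event onset outside the hypnogram span")
        events["state"] = hyp.labels[ep]
    counts = {s: int((events["state"] == s).sum()) for s in STATES} if len(events) \
        else {s: 0 for s in STATES}
    n_artifact = int((events["state"] == ARTIFACT).sum()) if len(events) else 0
    n_valid = sum(counts.values())
    hours = {s: hyp.hours_in_state(s) for s in STATES}
    summary = {
        "counts": counts,
        "n_events_in_artifact": n_artifact,
        "shares_pct": {s: (100.0 * counts[s] / n_valid if n_valid else np.nan)
                       for s in STATES},
        "rates_per_h": {s: (counts[s] / hours[s] if hours[s] > 0 else np.nan)
                        for s in STATES},
        "mean_duration_s": {
            s: (float((events.loc[events["state"] == s, "offset_s"]
                       - events.loc[events["state"] == s, "onset_s"]).mean())
                if counts[s] else np.nan) for s in STATES},
    }
    return events, summary


def epochs_containing_events(events: pd.DataFrame, hyp: Hypnogram,
                             rule: str = "overlap") -> np.ndarray:
    """Boolean mask over epochs: does any event touch epoch e?

    ``overlap`` counts any interval overlap with ``[e*L, (e+1)*L)``;
    ``onset`` counts only events whose onset falls inside the epoch.
    """
    mask = np.zeros(hyp.n_epochs, dtype=bool)
    if len(events) == 0:
        return mask
    L = hyp.epoch_len_s
    if rule == "onset":
        ep = hyp.epoch_of(events["onset_s"].to_numpy())
        mask[np.clip(ep, 0, hyp.n_epochs - 1)] = True
    elif rule == "overlap":
        first = np.floor(events["onset_s"].to_numpy() / L).astype(int)
        last = np.ceil(events["offset_s"].to_numpy() / L).astype(int) - 1
        for a, b in zip(first, last):
            mask[max(a, 0): min(b, hyp.n_epochs - 1) + 1] = True
    else:
        raise ValidationError("rule must be 'overlap' or 'onset'")
    return mask


def conditional_transitions(events: pd.DataFrame, hyp: Hypnogram,
                            rule: str = "overlap", n_boot: int = 1000,
                            seed: int = 0) -> dict:
    """Probability of a state transition after SWD-containing vs SWD-free epochs.

    A transition follows epoch e when ``label(e+1) != label(e)`` with both
    epochs artifact-free.  The SWD/clean ratio is reported with a seeded
    bootstrap interval over epochs (the interval is supplementary output,
    not an acceptance gate).
    """
    has_swd = epochs_containing_events(events, hyp, rule)
    ok = hyp.artifact_free()
    valid = ok[:-1] & ok[1:]
    trans = hyp.labels[:-1] != hyp.labels[1:]

    swd_mask = has_swd[:-1] & valid
    clean_mask = ~has_swd[:-1] & valid
    n_swd, n_clean = int(swd_mask.sum()), int(clean_mask.sum())
    if n_clean == 0:
        raise ValidationError("no SWD-free epochs with a successor")

    p_swd = float(trans[swd_mask].mean()) if n_swd else np.nan
    p_clean = float(trans[clean_mask].mean())
    ratio = (p_swd / p_clean) if (n_swd and p_clean > 0) else np.nan
    ratio_flag = None
    if n_swd == 0:
        ratio_flag = "no SWD-containing epochs"
    elif p_clean == 0:
        ratio_flag = "no transitions after clean epochs (ratio undefined)"

    pairs = {}
    for a, b in TRANSITION_PAIRS:
        from_a_swd = swd_mask & (hyp.labels[:-1] == a)
        from_a_clean = clean_mask & (hyp.labels[:-1] == a)
        pairs[f"{a}->{b}"] = {
            "p_given_swd": (float(((hyp.labels[1:] == b) & from_a_swd).sum()
                                  / from_a_swd.sum()) if from_a_swd.sum() else np.nan),
            "p_given_clean": (float(((hyp.labels[1:] == b) & from_a_clean).sum()
                                    / from_a_clean.sum()) if from_a_clean.sum() else np.nan),
        }

    ci = (np.nan, np.nan)
    if n_swd and n_boot:
        rng = np.random.default_rng(seed)
        swd_idx = np.flatnonzero(swd_mask)
        clean_idx = np.flatnonzero(clean_mask)
        boots = []
        for _ in range(n_boot):
            bs = rng.choice(swd_idx, n_swd, replace=True)
            bc = rng.choice(clean_idx, n_clean, replace=True)
            pc = trans[bc].mean()
            if pc > 0:
                boots.append(trans[bs].mean() / pc)
        if boots:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))

    return {
        "p_transition_given_swd": p_swd,
        "p_transition_given_clean": p_clean,
        "ratio": ratio,
        "ratio_flag": ratio_flag,
        "ratio_ci95": ci,
        "n_swd_epochs": n_swd,
        "n_clean_epochs": n_clean,
        "pair_conditional": pairs,
    }


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    n: int
    flag: str | None = None


def correlate_fragmentation(transition_counts, swd_counts) -> CorrelationResult:
    """Pearson correlation between per-animal transition and SWD counts."""
    x = np.asarray(swd_counts, dtype=float)
    y = np.asarray(transition_counts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need at least 3 animals with paired counts")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=np.nan, p=np.nan, slope=np.nan, n=len(x),
                                 flag="zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return CorrelationResult(r=float(r), p=float(p), slope=slope, n=len(x))
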