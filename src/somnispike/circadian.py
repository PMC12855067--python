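"""Circadian statistics of event occurrence.

Two complementary descriptions are computed from event Zeitgeber times:

* the **Rayleigh test** of circular uniformity on event phases
  ``theta = 2*pi*ZT/24``, with the small-sample-corrected p-value
  approximation ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))``
  (Zar, Biostatistical Analysis, 1999), where ``Rn = n*R`` is the resultant
  length — approximations differ between texts, so the exact formula is
  pinned here and its null calibration is enforced by a uniformity test in
  the suite;
* a **cosinor fit**: ordinary least squares of
  ``y = M + beta_c*cos(omega*t) + beta_s*sin(omega*t)`` at fixed 24-h
  period, reported as MESOR ``M``, amplitude ``A = sqrt(beta_c^2+beta_s^2)``
  and acrophase ``phi = atan2(-beta_s, beta_c)`` converted to ZT hours,
  with the zero-amplitude F test on (2, n-3) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import Hypnogram, ValidationError


@dataclass
class RayleighResult:
    n: int
    R: float
    Z: float
    p: float
    mean_phase_rad: float
    mean_zt_h: float


@dataclass
class CosinorResult:
    mesor: float
    amplitude: float
    acrophase_h: float
    f_stat: float
    p: float
    period_h: float = 24.0

    def predict(self, t_h: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (np.asarray(t_h) - self.acrophase_h) / self.period_h)


def hourly_histogram(events: pd.DataFrame, hyp: Hypnogram) -> pd.DataFrame:
    """Per-ZT-hour event counts and rates per minute spent in SWS.

    Returns 24 rows with columns ``zt_hour`` (bin ``[h, h+1)``), ``count``,
    ``sws_minutes`` and ``rate_per_sws_min`` (NaN where the hour holds no
    SWS time).
    """
    counts = np.zeros(24)
    if len(events):
        bins = np.floor(events["onset_zt_h"].to_numpy() % 24).astype(int)
        for b in bins:
            counts[b] += 1

    sws_min = np.zeros(24)
    ep_zt = hyp.epoch_zt(np.arange(hyp.n_epochs))
    sws_epochs = hyp.labels == "SWS"
    for h in range(24):
        in_bin = (ep_zt >= h) & (ep_zt < h + 1)
        sws_min[h] = np.sum(in_bin & sws_epochs) * hyp.epoch_len_s / 60.0

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(sws_min > 0, counts / sws_min, np.nan)
    return pd.DataFrame({"zt_hour": np.arange(24), "count": counts,
                         "sws_minutes": sws_min, "rate_per_sws_min": rate})


def rayleigh_test(event_zt_h) -> RayleighResult:
    """Rayleigh test of circular uniformity on event ZT phases."""
    zt = np.asarray(event_zt_h, dtype=float)
    n = len(zt)
    if n < 2:
        raise ValidationError("Rayleigh test needs at least 2 events")
    theta = 2 * np.pi * (zt % 24.0) / 24.0
    C, S = np.cos(theta).sum(), np.sin(theta).sum()
    Rn = np.hypot(C, S)
    R = Rn / n
    Z = n * R**2
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    mean_phase = float(np.arctan2(S, C) % (2 * np.pi))
    return RayleighResult(n=n, R=float(R), Z=float(Z), p=p,
                          mean_phase_rad=mean_phase,
                          mean_zt_h=mean_phase * 24 / (2 * np.pi))


def cosinor_fit(t_h, y, period_h: float = 24.0) -> CosinorResult:
    """Least-squares fit of a fixed-period cosine to (time, value) samples."""
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y) or len(t) < 4:
        raise ValidationError("cosinor needs at least 4 samples")
    phase = (t % period_h) / period_h
    if np.ptp(phase) < 1e-12:
        raise ValidationError("degenerate design: all times coincide modulo the period")
    omega = 2 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    # with y = M + bc*cos(wt) + bs*sin(wt) = M + A*cos(w*(t - phi)),
    # the peak time is phi = atan2(bs, bc)/w
    acrophase = float((np.arctan2(bs, bc) * period_h / (2 * np.pi)) % period_h)

    resid = y - X @ beta
    ss1 = float(resid @ resid)
    ss0 = float(np.sum((y - y.mean()) ** 2))
    df2 = len(y) - 3
    if df2 > 0 and ss1 > 0:
        f = ((ss0 - ss1) / 2) / (ss1 / df2)
        p = float(stats.f.sf(f, 2, df2))
    else:
        f, p = np.inf, 0.0
    return CosinorResult(mesor=float(mesor), amplitude=amplitude,
                         acrophase_h=acrophase, f_stat=float(f), p=p,
                         period_h=period_h)


def events_cosinor(events: pd.DataFrame, hyp: Hypnogram,
                   period_h: float = 24.0) -> CosinorResult:
    """Cosinor on hourly binned counts (the default presentation); an
    events-as-points alternative is available through :func:`cosinor_fit`."""
    hist = hourly_histogram(events, hyp)
    return cosinor_fit(hist["zt_hour"].to_numpy() + 0.5, hist["count"].to_numpy(),
                       period_h)


def circadian_summary(events: pd.DataFrame, hyp: Hypnogram) -> dict:
    """Histogram + Rayleigh + cosinor in one bundle (single recording day;
    multi-day pooling must be requested explicitly by concatenating tables)."""
    hist = hourly_histogram(events, hyp)
    out = {"histogram": hist}
    if len(events) >= 2:
        out["rayleigh"] = rayleigh_test(events["onset_zt_h"].to_numpy())
    else:
        out["rayleigh"] = None
    try:
        out["cosinor"] = events_cosinor(events, hyp)
    except ValidationError:
        out["cosinor"] = None
    return out
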