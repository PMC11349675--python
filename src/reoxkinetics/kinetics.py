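"""Monoexponential recovery fitting and the mean response time (MRT).

The recovery segment (end of work to the detected peak) is fitted with a
delayed monoexponential

    y(t) = y0 + A * (1 - exp(-(t - TD) / tau))   for t >= TD,   y(t) = y0 below,

with TD >= 0.  MRT = TD + tau is the time to recover ~63% of the amplitude.
A fit is accepted when pseudo-R² = 1 - SS_res/SS_tot >= 0.85 and MRT is
physiologically plausible: strictly between zero and the time of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import SmO2Trace
from .protocol import StageSchedule

__all__ = ["MonoExpFit", "fit_monoexp", "hrt_from_fit", "conformity_report", "fit_bouts"]

LN2 = log(2.0)

R2_THRESHOLD = 0.85
TAU_STARTS = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0)
DELAY_STARTS = (0.0, 5.0, 15.0)


@dataclass
class MonoExpFit:
    y0: float
    amp: float
    tau_s: float
    delay_s: float
    mrt_s: float
    pseudo_r2: float
    accepted: bool
    n_points: int
    t_peak_s: float
    reason: str = ""


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    y0, amp, tau, delay = params
    return y0 + amp * (1.0 - np.exp(-np.clip(t - delay, 0.0, None) / tau))


def fit_monoexp(
    t: np.ndarray,
    y: np.ndarray,
    t_peak_s: float | None = None,
) -> MonoExpFit:
    """Least-squares monoexponential fit of a recovery segment.

    ``t`` is seconds from the end of work; the segment should span end of
    work to the detected peak (``t_peak_s`` defaults to ``t[-1]``).  A
    deterministic multi-start over a (tau, delay) grid guards against local
    minima; the best converged start wins.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5:
        raise ValueError("need at least 5 usable samples to fit")
    if t_peak_s is None:
        t_peak_s = float(t[-1])
    amp0 = float(np.max(y) - y[0])
    if amp0 <= 0:
        raise ValueError("non-positive recovery amplitude")

    span = float(t[-1] - t[0])
    best = None
    for tau0 in TAU_STARTS:
        for d0 in DELAY_STARTS:
            if d0 >= span:
                continue
            try:
                res = least_squares(
                    lambda p: _model(p, t) - y,
                    x0=np.array([y[0], amp0, tau0, d0]),
                    bounds=(
                        np.array([-np.inf, 0.0, 1e-3, 0.0]),
                        np.array([np.inf, np.inf, np.inf, max(span, 1e-3)]),
                    ),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-12:
                best = res

    if best is None or not np.all(np.isfinite(best.x)):
        return MonoExpFit(
            y0=np.nan, amp=np.nan, tau_s=np.nan, delay_s=np.nan, mrt_s=np.nan,
            pseudo_r2=np.nan, accepted=False, n_points=int(t.size),
            t_peak_s=t_peak_s, reason="no converged fit",
        )

    y0, amp, tau, delay = best.x
    resid = _model(best.x, t) - y
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    mrt = delay + tau
    plausible = 0.0 < mrt < t_peak_s
    accepted = (r2 >= R2_THRESHOLD) and plausible
    reason = ""
    if not accepted:
        reason = "; ".join(
            r for r, bad in [
                (f"pseudo_r2 {r2:.3f} < {R2_THRESHOLD}", r2 < R2_THRESHOLD),
                (f"MRT {mrt:.1f}s outside (0, {t_peak_s:.0f}s)", not plausible),
            ] if bad
        )
    return MonoExpFit(
        y0=float(y0), amp=float(amp), tau_s=float(tau), delay_s=float(delay),
        mrt_s=float(mrt), pseudo_r2=float(r2), accepted=accepted,
        n_points=int(t.size), t_peak_s=float(t_peak_s), reason=reason,
    )


def hrt_from_fit(fit: MonoExpFit) -> float:
    """Analytic half-recovery time of an accepted fit: TD + tau * ln 2."""
    if not fit.accepted:
        raise ValueError("HRT is only computed from accepted fits")
    return fit.delay_s + fit.tau_s * LN2


def fit_bouts(
    bouts: pd.DataFrame,
    traces: Mapping[tuple, SmO2Trace],
    schedules: Mapping[str, StageSchedule] | StageSchedule,
) -> pd.DataFrame:
    """Fit every OK bout's recovery segment; append fit columns to the table.

    ``traces`` maps (participant_id, trial, site) to the analysis-rate trace.
    """
    rows = []
    for _, b in bouts.iterrows():
        row = dict(b)
        if b["status"] == "OK":
            sched = (
                schedules
                if isinstance(schedules, StageSchedule)
                else schedules[b["participant_id"]]
            )
            trace = traces[(b["participant_id"], b["trial"], b["site"])]
            work_end = sched.stage(int(b["stage_index"])).work_end_s
            sel = (
                (trace.t >= work_end)
                & (trace.t <= work_end + b["t_peak_s"])
                & trace.usable
            )
            try:
                fit = fit_monoexp(
                    trace.t[sel] - work_end, trace.y[sel], t_peak_s=float(b["t_peak_s"])
                )
                row.update(
                    fit_tau_s=fit.tau_s, fit_delay_s=fit.delay_s, fit_mrt_s=fit.mrt_s,
                    fit_pseudo_r2=fit.pseudo_r2, fit_accepted=fit.accepted,
                    fit_reason=fit.reason,
                )
            except ValueError as exc:
                row.update(
                    fit_tau_s=np.nan, fit_delay_s=np.nan, fit_mrt_s=np.nan,
                    fit_pseudo_r2=np.nan, fit_accepted=False, fit_reason=str(exc),
                )
        else:
            row.update(
                fit_tau_s=np.nan, fit_delay_s=np.nan, fit_mrt_s=np.nan,
                fit_pseudo_r2=np.nan, fit_accepted=False, fit_reason=b["status"],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def conformity_report(fits: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Fraction of attempted bouts whose fit was rejected, overall and by
    site × target workload."""
    if len(fits) == 0:
        raise ValueError("no fits to report on")
    attempted = fits[fits["status"] == "OK"] if "status" in fits else fits
    if len(attempted) == 0:
        raise ValueError("no fittable (OK) bouts")
    overall = float(1.0 - attempted["fit_accepted"].mean())
    by_cell = (
        attempted.groupby(["site", "pct_target"])["fit_accepted"]
        .agg(n="size", frac_rejected=lambda s: 1.0 - s.mean())
        .reset_index()
    )
    return overall, by_cell
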