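"""Per-bout reoxygenation extraction: end-work baseline, recovery peak, HRT.

After each work stage SmO₂ rises during the rest period.  A bout is
summarised by the mean SmO₂ over the final 30 s of work (Y_A), the recovery
peak (Y_B) — the first value in the recovery window with no strictly higher
value within the next 30 s — and the half-recovery time (HRT): the time from
the end of work until the signal first reaches Y_A + (Y_B − Y_A)/2, with
linear interpolation between the bracketing samples.

Recovery windows differ by muscle-site class: locomotor sites (VL, RF)
recover within the rest period, so the window runs to the next work start;
accessory sites (PS, DL) keep reoxygenating into the next stage and get an
extra 60 s; after the final stage every site gets 4 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import SmO2Trace, screen_quality, smooth_and_resample
from .protocol import StageSchedule

__all__ = [
    "BoutStatus",
    "ReoxBout",
    "LOCOMOTOR_SITES",
    "ACCESSORY_SITES",
    "end_work_baseline",
    "recovery_window",
    "detect_peak",
    "half_recovery_time",
    "extract_bout",
    "extract_all",
]

LOCOMOTOR_SITES = frozenset({"VL", "RF"})
ACCESSORY_SITES = frozenset({"PS", "DL"})

BASELINE_WINDOW_S = 30.0
PEAK_LOOKAHEAD_S = 30.0
FINAL_WINDOW_S = 240.0
ACCESSORY_EXTENSION_S = 60.0


class BoutStatus(str, Enum):
    OK = "OK"
    MISSING = "MISSING"
    ZERO_AMPLITUDE = "ZERO_AMPLITUDE"
    NO_PEAK = "NO_PEAK"
    QUALITY_FAIL = "QUALITY_FAIL"


@dataclass
class ReoxBout:
    participant_id: str
    trial: int
    site: str
    stage_index: int
    pct_wpeak: float
    pct_target: float
    y_a: float = np.nan
    y_b: float = np.nan
    t_peak_s: float = np.nan  # from end of work
    amplitude_pct: float = np.nan
    hrt_s: float = np.nan
    status: BoutStatus = BoutStatus.OK
    truncated_lookahead: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["status"] = self.status.value
        return d


def end_work_baseline(trace: SmO2Trace, work_end_s: float) -> float:
    """Mean SmO₂ (Y_A) over usable samples in the final 30 s of work."""
    sel = (trace.t >= work_end_s - BASELINE_WINDOW_S) & (trace.t < work_end_s) & trace.usable
    if not np.any(sel):
        raise ValueError("no usable samples in the end-work baseline window")
    return float(np.mean(trace.y[sel]))


def recovery_window(
    schedule: StageSchedule, stage_index: int, site: str
) -> tuple[float, float]:
    """Half-open recovery window [start, end) after a stage's work interval."""
    stage = schedule.stage(stage_index)
    is_final = stage_index == schedule.stages[-1].index
    if is_final:
        return stage.work_end_s, stage.work_end_s + FINAL_WINDOW_S
    next_start = schedule.stage(stage_index + 1).work_start_s
    if site in ACCESSORY_SITES:
        return stage.work_end_s, next_start + ACCESSORY_EXTENSION_S
    return stage.work_end_s, next_start


def detect_peak(
    trace: SmO2Trace,
    window: tuple[float, float],
    lookahead_s: float = PEAK_LOOKAHEAD_S,
) -> tuple[float, float, bool]:
    """Recovery peak Y_B: earliest usable sample with no strictly higher
    sample within the following ``lookahead_s`` seconds (inside the window).

    Returns ``(y_b, t_peak_abs, truncated)`` where ``truncated`` flags a peak
    whose lookahead was cut short by the window edge.  Raises ``ValueError``
    when fewer than two usable samples fall inside the window.
    """
    lo, hi = window
    sel = (trace.t >= lo) & (trace.t < hi) & trace.usable
    t = trace.t[sel]
    y = trace.y[sel]
    if t.size < 2:
        raise ValueError("fewer than two usable samples in recovery window")

    # future running max over (t_i, t_i + lookahead] via a monotone deque
    n = t.size
    future_max = np.full(n, -np.inf)
    from collections import deque

    dq: deque[int] = deque()  # indices ahead of i, y decreasing toward the back
    for i in range(n - 1, -1, -1):
        # drop indices beyond the lookahead horizon (deque is time-ordered)
        while dq and t[dq[0]] > t[i] + lookahead_s:
            dq.popleft()
        future_max[i] = y[dq[0]] if dq else -np.inf
        while dq and y[dq[-1]] <= y[i]:
            dq.pop()
        dq.append(i)

    qualifies = future_max <= y  # equal later values do not disqualify
    k = int(np.argmax(qualifies))
    truncated = bool(t[k] + lookahead_s > t[-1])
    return float(y[k]), float(t[k]), truncated


def half_recovery_time(
    trace: SmO2Trace,
    work_end_s: float,
    y_a: float,
    y_b: float,
    t_peak_abs: float,
) -> float:
    """Time from end of work to the half-amplitude crossing, interpolated.

    The threshold is Y_A + (Y_B − Y_A)/2; the crossing is located on the
    usable samples between work end and the peak, linearly interpolating
    between the last sample below and the first sample at/above threshold.
    """
    if y_b <= y_a:
        raise ValueError("zero or negative amplitude: y_b must exceed y_a")
    threshold = y_a + (y_b - y_a) / 2.0
    sel = (trace.t >= work_end_s) & (trace.t <= t_peak_abs) & trace.usable
    t = trace.t[sel]
    y = trace.y[sel]
    above = y >= threshold
    if not np.any(above):
        raise RuntimeError("threshold never reached before the detected peak")
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0] - work_end_s)
    t_cross = t[k - 1] + (threshold - y[k - 1]) / (y[k] - y[k - 1]) * (t[k] - t[k - 1])
    return float(t_cross - work_end_s)


def extract_bout(
    trace: SmO2Trace,
    schedule: StageSchedule,
    stage_index: int,
    pct_target: float = np.nan,
    max_missing_frac: float = 0.5,
) -> ReoxBout:
    """Run the full per-bout extraction with status accounting.

    Expects the analysis-rate (smoothed, screened) trace.  Failures become
    statuses, never exceptions: a bout with an unusable window is MISSING or
    QUALITY_FAIL, one with no positive amplitude is ZERO_AMPLITUDE, one where
    no peak can be located is NO_PEAK.
    """
    stage = schedule.stage(stage_index)
    bout = ReoxBout(
        participant_id=trace.participant_id,
        trial=trace.trial,
        site=trace.site,
        stage_index=stage_index,
        pct_wpeak=schedule.pct_wpeak(stage_index),
        pct_target=pct_target,
    )
    lo, hi = recovery_window(schedule, stage_index, trace.site)
    hi_eff = min(hi, float(trace.t[-1]) + 1e-9)

    in_win = (trace.t >= lo) & (trace.t < hi_eff)
    n_expected = int(np.sum(in_win))
    n_usable = int(np.sum(in_win & trace.usable))
    if n_expected == 0 or n_usable == 0:
        bout.status = BoutStatus.MISSING
        return bout
    if 1.0 - n_usable / n_expected > max_missing_frac:
        n_present = int(np.sum(in_win & np.isfinite(trace.y)))
        bout.status = (
            BoutStatus.MISSING
            if n_present - n_usable < n_expected - n_present
            else BoutStatus.QUALITY_FAIL
        )
        return bout

    try:
        bout.y_a = end_work_baseline(trace, stage.work_end_s)
    except ValueError:
        bout.status = BoutStatus.MISSING
        return bout
    try:
        y_b, t_peak_abs, truncated = detect_peak(trace, (lo, hi_eff))
    except ValueError:
        bout.status = BoutStatus.NO_PEAK
        return bout
    bout.y_b = y_b
    bout.t_peak_s = t_peak_abs - stage.work_end_s
    bout.amplitude_pct = y_b - bout.y_a
    bout.truncated_lookahead = truncated
    if bout.amplitude_pct <= 0:
        bout.status = BoutStatus.ZERO_AMPLITUDE
        return bout
    bout.hrt_s = half_recovery_time(trace, stage.work_end_s, bout.y_a, y_b, t_peak_abs)
    return bout


def _select_stage(schedule: StageSchedule, pct_target: float, tolerance_pct: float) -> int | None:
    best, best_d = None, np.inf
    for s in schedule.stages:
        d = abs(schedule.pct_wpeak(s.index) - pct_target)
        if d < best_d:
            best, best_d = s.index, d
    return best if best_d <= tolerance_pct else None


def extract_all(
    traces: Iterable[SmO2Trace],
    schedules: Mapping[str, StageSchedule] | StageSchedule,
    targets: Sequence[float] = (50.0, 75.0, 100.0),
    tolerance_pct: float = 6.0,
    preprocess: bool = True,
    window_s: float = 5.0,
    max_jump_pct: float = 10.0,
    max_missing_frac: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Extract one bout per trace × target workload; report bout accounting.

    ``schedules`` maps participant_id → schedule (or one shared schedule).
    Raw 0.5 Hz traces are smoothed/resampled/screened unless ``preprocess``
    is False.  Returns the tidy bout table plus a summary dict with the
    number of scheduled bouts, unusable bouts, and the unusable percentage
    (one decimal).
    """
    rows: list[dict] = []
    for trace in traces:
        sched = (
            schedules if isinstance(schedules, StageSchedule) else schedules[trace.participant_id]
        )
        if preprocess:
            trace = screen_quality(smooth_and_resample(trace, window_s=window_s), max_jump_pct)
        for target in targets:
            idx = _select_stage(sched, target, tolerance_pct)
            if idx is None:
                continue
            bout = extract_bout(trace, sched, idx, pct_target=target, max_missing_frac=max_missing_frac)
            rows.append(bout.to_dict())
    table = pd.DataFrame(rows)
    n_sched = len(table)
    n_bad = int((table["status"] != BoutStatus.OK.value).sum()) if n_sched else 0
    accounting = {
        "bouts_scheduled": n_sched,
        "bouts_unusable": n_bad,
        "pct_unusable": round(100.0 * n_bad / n_sched, 1) if n_sched else np.nan,
    }
    return table, accounting
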