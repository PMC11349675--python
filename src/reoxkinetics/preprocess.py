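"""Raw SmO₂ trace container, I/O, smoothing/resampling, and quality screening.

Wearable NIRS devices report muscle oxygen saturation (SmO₂, %) at a low
native rate (0.5 Hz here).  The analysis series is that signal smoothed with
a symmetric 5-s moving average and resampled to 1 Hz — the manufacturer's
recommended processing.  Since 1 Hz is above the native rate this is an
upsample: we smooth on the native grid first and then linearly interpolate;
the choice is recorded in the trace metadata.

Missing samples are carried as NaN throughout; the per-sample boolean
``quality_mask`` marks samples judged usable (present and not flagged by the
jump screen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SmO2Trace", "read_trace", "smooth_and_resample", "screen_quality"]


@dataclass
class SmO2Trace:
    """One SmO₂ recording with participant/trial/site metadata.

    ``t`` is strictly increasing (seconds from recording start); ``y`` holds
    SmO₂ in percent with NaN for missing samples.
    """

    t: np.ndarray
    y: np.ndarray
    participant_id: str = ""
    trial: int = 1
    site: str = ""
    rate_hz: float = 0.5
    quality_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        finite = np.isfinite(self.y)
        if np.any(finite & ((self.y < 0) | (self.y > 100))):
            raise ValueError("SmO2 samples must lie in [0, 100] or be missing")
        if self.quality_mask is None:
            self.quality_mask = finite.copy()
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool) & finite

    @property
    def usable(self) -> np.ndarray:
        return self.quality_mask & np.isfinite(self.y)

    def copy(self) -> "SmO2Trace":
        return replace(
            self,
            t=self.t.copy(),
            y=self.y.copy(),
            quality_mask=self.quality_mask.copy(),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "smo2_pct": self.y})


def read_trace(
    path: str | Path,
    participant_id: str = "",
    trial: int = 1,
    site: str = "",
    rate_hz: float = 0.5,
) -> SmO2Trace:
    """Read a two-column CSV (header ``time_s, smo2_pct``) into a trace.

    Out-of-range SmO₂ values are marked missing with a warning; duplicated or
    non-monotone timestamps are a hard error.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise IOError(f"could not parse {path}: {exc}") from exc
    for col in ("time_s", "smo2_pct"):
        if col not in df.columns:
            raise IOError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["smo2_pct"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    bad = np.isfinite(y) & ((y < 0) | (y > 100))
    if np.any(bad):
        warnings.warn(
            f"{path}: {int(bad.sum())} SmO2 sample(s) outside [0, 100] marked missing",
            stacklevel=2,
        )
        y = y.copy()
        y[bad] = np.nan
    return SmO2Trace(
        t=t, y=y, participant_id=participant_id, trial=trial, site=site, rate_hz=rate_hz
    )


def smooth_and_resample(
    trace: SmO2Trace, window_s: float = 5.0, out_rate_hz: float = 1.0
) -> SmO2Trace:
    """Symmetric moving average of total span ``window_s`` then linear
    resampling to ``out_rate_hz``.

    Edges use shrunken (partial) windows; missing samples are excluded from
    window means, and windows containing no usable samples stay missing.
    Resampled points falling between a missing smoothed sample and anything
    else are missing too (no interpolation across gaps).
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    t, y = trace.t, trace.y
    usable = trace.usable
    half = window_s / 2.0
    n = t.size

    smoothed = np.full(n, np.nan)
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    yv = np.where(usable, y, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(yv)])
    cnt = np.concatenate([[0], np.cumsum(usable.astype(int))])
    counts = cnt[hi] - cnt[lo]
    with np.errstate(invalid="ignore"):
        means = (cum[hi] - cum[lo]) / np.where(counts > 0, counts, 1)
    smoothed = np.where(counts > 0, means, np.nan)

    # 1 Hz grid over the same span; duration preserved within one period
    dt = 1.0 / out_rate_hz
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    idx = np.searchsorted(t, grid, side="right")
    left = np.clip(idx - 1, 0, n - 1)
    right = np.clip(idx, 0, n - 1)
    exact = np.isclose(grid, t[left])
    yl, yr = smoothed[left], smoothed[right]
    tl, tr = t[left], t[right]
    span = np.where(tr > tl, tr - tl, 1.0)
    frac = (grid - tl) / span
    out = yl + frac * (yr - yl)
    out = np.where(exact, smoothed[left], out)
    valid = np.where(exact, np.isfinite(smoothed[left]), np.isfinite(yl) & np.isfinite(yr))
    out = np.where(valid, out, np.nan)
    out = np.clip(out, 0.0, 100.0)

    meta = dict(trace.meta)
    meta.update(
        smoothing_window_s=window_s,
        smoothing="centered moving average on native grid",
        resampling=f"linear interpolation to {out_rate_hz} Hz",
    )
    return SmO2Trace(
        t=grid,
        y=out,
        participant_id=trace.participant_id,
        trial=trace.trial,
        site=trace.site,
        rate_hz=out_rate_hz,
        meta=meta,
    )


def screen_quality(trace: SmO2Trace, max_jump_pct: float = 10.0) -> SmO2Trace:
    """Flag samples adjacent to implausible sample-to-sample jumps.

    A jump of more than ``max_jump_pct`` %SmO₂ between consecutive present
    samples marks both endpoints unusable.  Idempotent: flagging does not
    change ``y``, so re-screening flags the same samples.
    """
    if max_jump_pct <= 0:
        raise ValueError("max_jump_pct must be > 0")
    out = trace.copy()
    y = out.y
    finite = np.isfinite(y)
    idx = np.flatnonzero(finite)
    if idx.size >= 2:
        jumps = np.abs(np.diff(y[idx]))
        bad = jumps > max_jump_pct
        out.quality_mask[idx[:-1][bad]] = False
        out.quality_mask[idx[1:][bad]] = False
    out.meta["jump_screen_pct"] = max_jump_pct
    return out
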