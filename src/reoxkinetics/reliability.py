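"""Test-retest reliability battery: CVs, ICC(2,1), SEM, MDC, and reports.

All agreement statistics derive from the two-way random-effects ANOVA of the
participants × trials matrix:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

(absolute agreement, single measure), SEM = sqrt(MS_E) in original units,
and MDC = 1.96 * sqrt(2) * SEM for 95% confidence.  ICC confidence intervals
use the standard F-based (McGraw & Wong) method; the SEM interval comes from
chi-square bounds on MS_E.  Between-participant CV is SD/mean of participant
trial means; within-participant CV is the root mean square of each
participant's own trial CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityCell",
    "between_cv",
    "icc_2_1",
    "sem_mdc",
    "within_cv",
    "icc_band",
    "build_reports",
]

MDC_MULTIPLIER = 1.96 * np.sqrt(2.0)


@dataclass
class ReliabilityCell:
    site: str
    pct_wpeak_target: float
    n: int
    median_s: float
    q1_s: float
    q3_s: float
    cv_between_pct: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    sem_s: float
    sem_ci_low: float
    sem_ci_high: float
    mdc_s: float
    cv_within_pct: float
    icc_band: str


def _as_matrix(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a participants x trials matrix")
    X = X[~np.isnan(X).any(axis=1)]  # listwise deletion
    return X


def _mean_squares(X: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_r), float(ms_c), float(ms_e), n, k


def between_cv(values) -> float:
    """Between-participant CV (%): 100 * SD / mean of per-participant values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two participants")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def icc_2_1(matrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Rows with any missing trial are dropped listwise; needs >= 3 complete
    rows.  Returns (icc, ci_low, ci_high) with the F-based 95% CI.
    """
    X = _as_matrix(matrix)
    if X.shape[0] < 3:
        raise ValueError("ICC needs at least 3 complete participants")
    ms_r, ms_c, ms_e, n, k = _mean_squares(X)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (ms_r - ms_e) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    if ms_e == 0:
        return float(icc), float(icc), float(icc)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), float(icc), float(icc)
    v = (a * ms_c + b * ms_e) ** 2 / (
        (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (
        n * (ms_r - f_l * ms_e)
        / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    )
    hi = (
        n * (f_u * ms_r - ms_e)
        / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r)
    )
    return float(icc), float(lo), float(hi)


def sem_mdc(matrix, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """SEM = sqrt(MS_E) with chi-square CI, and MDC = 1.96 * sqrt(2) * SEM."""
    X = _as_matrix(matrix)
    if X.shape[0] < 3:
        raise ValueError("SEM needs at least 3 complete participants")
    _, _, ms_e, n, k = _mean_squares(X)
    sem = float(np.sqrt(ms_e))
    df_e = (n - 1) * (k - 1)
    if ms_e == 0:
        ci = (0.0, 0.0)
    else:
        lo = np.sqrt(df_e * ms_e / stats.chi2.ppf(1 - alpha / 2, df_e))
        hi = np.sqrt(df_e * ms_e / stats.chi2.ppf(alpha / 2, df_e))
        ci = (float(lo), float(hi))
    return sem, ci, float(MDC_MULTIPLIER * sem)


def within_cv(matrix) -> float:
    """Within-participant CV (%): RMS over participants of trial SD / trial mean."""
    X = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least two complete participants")
    s = X.std(axis=1, ddof=1)
    m = X.mean(axis=1)
    if np.any(m == 0):
        raise ValueError("within-participant CV undefined for a zero trial mean")
    return float(100.0 * np.sqrt(np.mean(s**2 / m**2)))


def icc_band(icc: float) -> str:
    """Interpretation bands: poor <0.5, moderate 0.5-0.75, good 0.75-0.9,
    excellent >0.9."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def _cell_matrix(cell: pd.DataFrame, n_trials: int = 2) -> np.ndarray:
    wide = cell.pivot_table(
        index="participant_id", columns="trial", values="hrt_s", aggfunc="mean"
    )
    for tr in range(1, n_trials + 1):
        if tr not in wide.columns:
            wide[tr] = np.nan
    return wide[sorted(wide.columns)].to_numpy(dtype=float)


def build_reports(
    bouts: pd.DataFrame,
    targets=(50.0, 75.0, 100.0),
    sites=("VL", "RF", "PS", "DL"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the descriptive and reliability tables, one row per
    site × target workload.

    Descriptives (medians, quartiles, between-participant CV) pool trials
    within participant by mean first, and count participants with at least
    one usable trial; the reliability table uses only participants with both
    trials (listwise), so its n can only be smaller.  Quartiles use linear
    interpolation between order statistics.
    """
    ok = bouts[bouts["status"] == "OK"]
    desc_rows, rel_rows = [], []
    for site in sites:
        for target in targets:
            cell = ok[(ok["site"] == site) & (ok["pct_target"] == target)]
            per_part = cell.groupby("participant_id")["hrt_s"].mean()
            d = {
                "site": site,
                "pct_target": target,
                "n": int(per_part.size),
                "median_s": np.nan, "q1_s": np.nan, "q3_s": np.nan,
                "cv_between_pct": np.nan,
            }
            if per_part.size:
                d["median_s"] = float(per_part.median())
                d["q1_s"] = float(per_part.quantile(0.25))
                d["q3_s"] = float(per_part.quantile(0.75))
            if per_part.size >= 2:
                d["cv_between_pct"] = between_cv(per_part.to_numpy())
            desc_rows.append(d)

            X = _cell_matrix(cell) if len(cell) else np.empty((0, 2))
            complete = X[~np.isnan(X).any(axis=1)] if X.size else X
            r = {
                "site": site, "pct_target": target, "n": int(complete.shape[0]),
                "icc": np.nan, "icc_ci_low": np.nan, "icc_ci_high": np.nan,
                "sem_s": np.nan, "sem_ci_low": np.nan, "sem_ci_high": np.nan,
                "mdc_s": np.nan, "cv_within_pct": np.nan, "icc_band": "",
            }
            if complete.shape[0] >= 3:
                try:
                    r["icc"], r["icc_ci_low"], r["icc_ci_high"] = icc_2_1(complete)
                    r["icc_band"] = icc_band(r["icc"])
                except ValueError:
                    pass
                sem, ci, mdc = sem_mdc(complete)
                r["sem_s"], (r["sem_ci_low"], r["sem_ci_high"]), r["mdc_s"] = sem, ci, mdc
                try:
                    r["cv_within_pct"] = within_cv(complete)
                except ValueError:
                    pass
            rel_rows.append(r)
    return pd.DataFrame(desc_rows), pd.DataFrame(rel_rows)
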