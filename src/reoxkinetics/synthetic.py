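"""Synthetic wearable-NIRS SmO₂ study generator.

Emulates the statistical structure the analysis pipeline assumes: during
each work stage SmO₂ decays monoexponentially toward a workload-dependent
plateau; during rest it recovers, after a site-specific onset delay, back
toward the pre-work baseline with a time constant that grows with relative
workload,

    tau(p) = tau_base * (1 + tau_slope * (p - 0.5)),    p = workload / Wpeak.

Accessory muscle sites (paraspinals, deltoid) keep reoxygenating into the
start of the next work stage (the muscle-pump effect) before deoxygenation
resumes, so their recovery peaks fall inside the extended recovery window.

Between-participant variability enters as a lognormal factor on tau shared
across sites (plus a smaller site-specific lognormal jitter), between-trial
variability as a further lognormal factor, and measurement noise as
additive Gaussian samples; the signal is clipped to the device's 0-100%
range.  Traces are emitted at the device's native 0.5 Hz.

Default site profiles are tuned so the analytic half-recovery times
(delay + tau * ln 2, truncated by the recovery window) land in the ranges
typical for trained cyclists: fastest in the vastus lateralis, slower in
order VL < RF < PS < DL, and slowing with workload in all but the deltoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SmO2Trace
from .protocol import Stage, StageSchedule, build_schedule

__all__ = [
    "SiteKineticsProfile",
    "PopulationConfig",
    "StudyData",
    "DEFAULT_PROFILES",
    "SITES",
    "simulate_trace",
    "simulate_study",
    "inject_artifact",
    "inject_missing_bouts",
    "monoexp_bout_trace",
    "write_study",
]

LN2 = math.log(2.0)
SITES = ("VL", "RF", "PS", "DL")

# default study conditions: 21 trained cyclists, two trials, mass 69.6 (11.3) kg
DEFAULT_BODY_MASS_MEAN = 69.6
DEFAULT_BODY_MASS_SD = 11.3


@dataclass(frozen=True)
class SiteKineticsProfile:
    """Per-muscle-site kinetics of the piecewise work/rest SmO₂ model."""

    site: str
    tau_base_s: float  # reoxygenation time constant at 50% Wpeak
    tau_slope: float  # multiplicative tau increase per unit fractional %Wpeak
    delay_s: float  # reoxygenation onset delay after work end
    deoxy_amplitude_pct: float  # desaturation depth at 100% Wpeak
    deoxy_tau_s: float  # work-phase kinetics
    baseline_pct: float  # resting SmO₂
    work_onset_delay_s: float = 0.0  # recovery continues this long into next work
    overshoot_pct: float = 0.0  # supra-baseline recovery target

    def __post_init__(self) -> None:
        if self.tau_base_s <= 0 or self.deoxy_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.baseline_pct <= 100.0:
            raise ValueError("baseline_pct must be in [0, 100]")
        if self.delay_s < 0 or self.work_onset_delay_s < 0:
            raise ValueError("delays must be non-negative")

    def tau_at(self, pct_wpeak: float) -> float:
        """Recovery time constant at a workload given as % of Wpeak."""
        return self.tau_base_s * (1.0 + self.tau_slope * (pct_wpeak / 100.0 - 0.5))


DEFAULT_PROFILES: dict[str, SiteKineticsProfile] = {
    "VL": SiteKineticsProfile("VL", tau_base_s=11.5, tau_slope=2.26, delay_s=0.0,
                              deoxy_amplitude_pct=40.0, deoxy_tau_s=25.0, baseline_pct=70.0),
    "RF": SiteKineticsProfile("RF", tau_base_s=23.1, tau_slope=1.75, delay_s=2.0,
                              deoxy_amplitude_pct=35.0, deoxy_tau_s=25.0, baseline_pct=70.0),
    "PS": SiteKineticsProfile("PS", tau_base_s=30.3, tau_slope=1.23, delay_s=5.0,
                              deoxy_amplitude_pct=25.0, deoxy_tau_s=30.0, baseline_pct=65.0,
                              work_onset_delay_s=30.0),
    "DL": SiteKineticsProfile("DL", tau_base_s=40.4, tau_slope=0.43, delay_s=8.0,
                              deoxy_amplitude_pct=20.0, deoxy_tau_s=30.0, baseline_pct=60.0,
                              work_onset_delay_s=45.0),
}


@dataclass
class PopulationConfig:
    """Study-level generative settings (all SDs on the log-tau scale except
    the additive measurement noise)."""

    n_participants: int = 21
    n_trials: int = 2
    between_sd: float = 0.35  # participant lognormal SD on tau, shared across sites
    site_sd: float = 0.12  # additional participant-by-site lognormal SD
    within_sd: float = 0.20  # between-trial lognormal SD on tau
    noise_sd_pct: float = 1.5  # additive sample noise, %SmO₂
    artifact_rate: float = 0.0  # per-bout probability of an injected artifact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("need at least one participant and one trial")
        if min(self.between_sd, self.site_sd, self.within_sd, self.noise_sd_pct) < 0:
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass
class StudyData:
    traces: list[SmO2Trace]
    schedules: dict[str, StageSchedule]
    truth: pd.DataFrame
    config: PopulationConfig

    @property
    def trace_map(self) -> dict[tuple, SmO2Trace]:
        return {(tr.participant_id, tr.trial, tr.site): tr for tr in self.traces}


def simulate_trace(
    schedule: StageSchedule,
    profile: SiteKineticsProfile,
    seed: int | np.random.SeedSequence | None = None,
    tau_factor: float = 1.0,
    amp_factor: float = 1.0,
    baseline_shift: float = 0.0,
    noise_sd_pct: float = 0.0,
    rate_hz: float = 0.5,
    tail_s: float = 260.0,
    participant_id: str = "",
    trial: int = 1,
) -> SmO2Trace:
    """Simulate one SmO₂ recording over a full protocol.

    The signal is stepped sample-by-sample with the exact relaxation update
    y <- target + (y - target) * exp(-dt/tau) for the phase active at each
    instant, which keeps the model well-behaved across phase boundaries.
    ``tail_s`` extends the recording past the final work stage so the 4-min
    final recovery window is covered.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    duration = schedule.stages[-1].work_end_s + tail_s
    t = np.arange(0.0, duration + dt / 2, dt)

    baseline = float(np.clip(profile.baseline_pct + baseline_shift, 5.0, 95.0))
    recovery_target = min(baseline + profile.overshoot_pct, 100.0)

    def mode_at(tt: float):
        """Return (kind, target, tau) for the instant tt."""
        stage = None
        for s in schedule.stages:
            if s.work_start_s <= tt < s.rest_end_s:
                stage = s
                break
        if stage is None:  # past the final scheduled rest: keep recovering
            last = schedule.stages[-1]
            if tt - last.work_end_s < profile.delay_s:
                return "hold", 0.0, 1.0
            return "relax", recovery_target, profile.tau_at(
                schedule.pct_wpeak(last.index)) * tau_factor
        in_work = tt < stage.work_end_s
        if in_work:
            since_start = tt - stage.work_start_s
            if stage.index > 1 and since_start < profile.work_onset_delay_s:
                prev = schedule.stage(stage.index - 1)
                return "relax", recovery_target, profile.tau_at(
                    schedule.pct_wpeak(prev.index)) * tau_factor
            depth = profile.deoxy_amplitude_pct * amp_factor * (
                schedule.pct_wpeak(stage.index) / 100.0)
            target = max(baseline - depth, 2.0)
            return "relax", target, profile.deoxy_tau_s
        since_end = tt - stage.work_end_s
        if since_end < profile.delay_s:
            return "hold", 0.0, 1.0
        return "relax", recovery_target, profile.tau_at(
            schedule.pct_wpeak(stage.index)) * tau_factor

    # phase-change instants; steps are split here so each sub-interval is a
    # single exact exponential relaxation (or hold) — no onset quantization
    events: set[float] = set()
    for s in schedule.stages:
        events.update((
            s.work_start_s, s.work_start_s + profile.work_onset_delay_s,
            s.work_end_s, s.work_end_s + profile.delay_s, s.rest_end_s,
        ))
    event_arr = np.array(sorted(e for e in events if 0.0 < e < duration + dt))

    y = np.empty_like(t)
    y[0] = baseline
    cur = baseline
    for i in range(1, t.size):
        seg_start, seg_stop = t[i - 1], t[i]
        pos = seg_start
        while pos < seg_stop - 1e-12:
            j = np.searchsorted(event_arr, pos, side="right")
            nxt = event_arr[j] if j < event_arr.size else seg_stop
            sub_end = min(nxt, seg_stop)
            kind, target, tau = mode_at(pos)
            if kind == "relax":
                cur = target + (cur - target) * math.exp(-(sub_end - pos) / tau)
            pos = sub_end
        y[i] = cur

    if noise_sd_pct > 0:
        y = y + rng.normal(0.0, noise_sd_pct, size=y.shape)
    y = np.clip(y, 0.0, 100.0)
    return SmO2Trace(
        t=t, y=y, participant_id=participant_id, trial=trial, site=profile.site,
        rate_hz=rate_hz, meta={"synthetic": True},
    )


def _stream(*keys: int) -> np.random.SeedSequence:
    """Counter-based substream: draws for one entity never perturb another."""
    return np.random.SeedSequence(entropy=list(keys))


def simulate_study(
    pop: PopulationConfig,
    profiles: dict[str, SiteKineticsProfile] | None = None,
    n_stages: int = 7,
    targets: tuple[float, ...] = (50.0, 75.0, 100.0),
) -> StudyData:
    """Simulate a full study: one trace per participant × trial × site plus a
    ground-truth table of per-bout (tau, delay, amplitude, analytic HRT).

    The default seven-stage ramp (1.0 + 0.5 W·kg⁻¹ per stage, all stages
    completed) puts stages at exactly 50, 75, and 100% of Wpeak.  Identical
    config (including seed) gives identical output.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    sites = tuple(profiles)
    traces: list[SmO2Trace] = []
    schedules: dict[str, StageSchedule] = {}
    truth_rows: list[dict] = []

    for p in range(pop.n_participants):
        pid = f"P{p + 1:02d}"
        rng_p = np.random.default_rng(_stream(pop.seed, 1, p))
        mass = float(np.clip(
            rng_p.normal(DEFAULT_BODY_MASS_MEAN, DEFAULT_BODY_MASS_SD), 45.0, 110.0))
        g_tau = math.exp(rng_p.normal(0.0, pop.between_sd))
        schedule = build_schedule(1.0, 0.5, n_stages, mass)
        schedules[pid] = schedule

        for s_i, site in enumerate(sites):
            rng_ps = np.random.default_rng(_stream(pop.seed, 2, p, s_i))
            site_jit = math.exp(rng_ps.normal(0.0, pop.site_sd))
            amp_factor = math.exp(rng_ps.normal(0.0, 0.10))
            baseline_shift = float(rng_ps.normal(0.0, 3.0))
            profile = profiles[site]

            for trial in range(1, pop.n_trials + 1):
                rng_pts = np.random.default_rng(_stream(pop.seed, 3, p, s_i, trial))
                u = math.exp(rng_pts.normal(0.0, pop.within_sd))
                tau_factor = g_tau * site_jit * u
                trace = simulate_trace(
                    schedule, profile,
                    seed=_stream(pop.seed, 4, p, s_i, trial),
                    tau_factor=tau_factor, amp_factor=amp_factor,
                    baseline_shift=baseline_shift, noise_sd_pct=pop.noise_sd_pct,
                    participant_id=pid, trial=trial,
                )
                if pop.artifact_rate > 0:
                    trace = _maybe_inject_artifacts(
                        trace, schedule, site, targets, pop, p, s_i, trial)
                traces.append(trace)

                for target in targets:
                    idx = min(
                        (s.index for s in schedule.stages),
                        key=lambda k: abs(schedule.pct_wpeak(k) - target),
                    )
                    tau_eff = profile.tau_at(schedule.pct_wpeak(idx)) * tau_factor
                    truth_rows.append({
                        "participant_id": pid, "trial": trial, "site": site,
                        "stage_index": idx, "pct_target": target,
                        "tau_s": tau_eff, "delay_s": profile.delay_s,
                        "amplitude_pct": profile.deoxy_amplitude_pct * amp_factor
                        * schedule.pct_wpeak(idx) / 100.0,
                        "hrt_analytic_s": profile.delay_s + tau_eff * LN2,
                    })

    return StudyData(
        traces=traces, schedules=schedules,
        truth=pd.DataFrame(truth_rows), config=pop,
    )


def _maybe_inject_artifacts(trace, schedule, site, targets, pop, p, s_i, trial):
    from .reoxygenation import recovery_window

    rng = np.random.default_rng(_stream(pop.seed, 5, p, s_i, trial))
    for target in targets:
        idx = min((s.index for s in schedule.stages),
                  key=lambda k: abs(schedule.pct_wpeak(k) - target))
        if rng.random() < pop.artifact_rate:
            window = recovery_window(schedule, idx, site)
            mode = "dropout" if rng.random() < 0.5 else "noise-burst"
            trace = inject_artifact(trace, window, mode, seed=rng.integers(2**31))
    return trace


def inject_artifact(
    trace: SmO2Trace,
    window: tuple[float, float],
    mode: str = "dropout",
    noise_sd_pct: float = 30.0,
    seed: int | None = None,
) -> SmO2Trace:
    """Corrupt a time window: ``dropout`` removes samples, ``noise-burst``
    adds high-variance noise (clipped to [0, 100])."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("artifact window must have positive length")
    out = trace.copy()
    sel = (out.t >= lo) & (out.t < hi)
    if not np.any(sel):
        raise ValueError("artifact window contains no samples")
    if mode == "dropout":
        out.y[sel] = np.nan
        out.quality_mask[sel] = False
    elif mode == "noise-burst":
        rng = np.random.default_rng(seed)
        out.y[sel] = np.clip(
            out.y[sel] + rng.normal(0.0, noise_sd_pct, size=int(sel.sum())), 0.0, 100.0)
    else:
        raise ValueError(f"unknown artifact mode {mode!r}")
    return out


def inject_missing_bouts(study: StudyData, n_bouts: int, seed: int = 0) -> StudyData:
    """Drop the full recovery window of ``n_bouts`` distinct scheduled bouts
    so downstream extraction reports exactly that many MISSING bouts."""
    from .reoxygenation import recovery_window

    targets = sorted(study.truth["pct_target"].unique())
    cells = [
        (tr.participant_id, tr.trial, tr.site, target)
        for tr in study.traces
        for target in targets
    ]
    rng = np.random.default_rng(seed)
    chosen = [cells[i] for i in rng.choice(len(cells), size=n_bouts, replace=False)]
    chosen_set = set(chosen)
    new_traces = []
    for tr in study.traces:
        sched = study.schedules[tr.participant_id]
        for target in targets:
            if (tr.participant_id, tr.trial, tr.site, target) in chosen_set:
                idx = min((s.index for s in sched.stages),
                          key=lambda k: abs(sched.pct_wpeak(k) - target))
                tr = inject_artifact(tr, recovery_window(sched, idx, tr.site), "dropout")
        new_traces.append(tr)
    return StudyData(new_traces, study.schedules, study.truth, study.config)


def monoexp_bout_trace(
    tau_s: float,
    delay_s: float = 0.0,
    amplitude_pct: float = 30.0,
    baseline_pct: float = 70.0,
    noise_sd_pct: float = 0.0,
    seed: int | None = None,
    site: str = "VL",
) -> tuple[SmO2Trace, StageSchedule, int]:
    """Single clean reoxygenation bout for oracle checks.

    Builds a two-stage schedule whose first rest period is long enough
    (≥ 12 tau) for the recovery to complete, so the extracted half-recovery
    time can be compared against the closed form delay + tau * ln 2.
    Returns (raw trace, schedule, bout stage index).
    """
    rest = max(300.0, math.ceil(12.0 * tau_s))
    work = 300.0
    stages = (
        Stage(1, 2.0, 140.0, 0.0, work, work + rest),
        Stage(2, 2.5, 175.0, work + rest, 2 * work + rest, 2 * work + rest + 60.0),
    )
    schedule = StageSchedule(stages=stages, body_mass_kg=70.0, wpeak_w=175.0)
    profile = SiteKineticsProfile(
        site=site, tau_base_s=tau_s, tau_slope=0.0, delay_s=delay_s,
        deoxy_amplitude_pct=amplitude_pct / (schedule.pct_wpeak(1) / 100.0),
        deoxy_tau_s=25.0, baseline_pct=baseline_pct,
    )
    trace = simulate_trace(
        schedule, profile, seed=seed, noise_sd_pct=noise_sd_pct, tail_s=260.0)
    return trace, schedule, 1


def write_study(study: StudyData, outdir: str | Path) -> pd.DataFrame:
    """Write one CSV per trace plus manifest and ground-truth CSVs.

    Missing samples are written as empty fields.  Output is deterministic
    for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in study.traces:
        name = f"{tr.participant_id}_T{tr.trial}_{tr.site}.csv"
        tr.to_frame().to_csv(outdir / name, index=False, float_format="%.4f")
        rows.append({"participant": tr.participant_id, "trial": tr.trial,
                     "site": tr.site, "file": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    study.truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    return manifest
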