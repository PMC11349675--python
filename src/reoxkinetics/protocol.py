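"""Incremental multi-stage cycling protocol: stage schedule and time → phase mapping.

The protocol alternates fixed-length work stages with short passive rest
periods.  Workload increases by a fixed increment (in W·kg⁻¹) each stage.
Peak workload (Wpeak) is the highest completed workload, prorated by the
completed fraction of the final stage.  All times are seconds from recording
start, with half-open phase intervals [start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "Phase",
    "Stage",
    "StageSchedule",
    "build_schedule",
    "compute_wpeak",
    "phase_at",
    "load_schedule",
]


class Phase(str, Enum):
    WORK = "WORK"
    REST = "REST"


@dataclass(frozen=True)
class Stage:
    """One work+rest block of the incremental protocol."""

    index: int  # 1-based
    workload_wkg: float  # relative power, W·kg⁻¹
    workload_w: float  # absolute power, W
    work_start_s: float
    work_end_s: float
    rest_end_s: float

    def __post_init__(self) -> None:
        if not (self.work_start_s < self.work_end_s <= self.rest_end_s):
            raise ValueError(
                f"stage {self.index}: require work_start < work_end <= rest_end, "
                f"got {self.work_start_s}, {self.work_end_s}, {self.rest_end_s}"
            )
        if self.index < 1:
            raise ValueError("stage index is 1-based")


@dataclass
class StageSchedule:
    """Ordered, contiguous work/rest stages plus the quantities needed to
    express each stage as a fraction of peak workload."""

    stages: tuple[Stage, ...]
    body_mass_kg: float
    wpeak_w: float | None = None
    final_stage_completed_fraction: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        for a, b in zip(self.stages, self.stages[1:]):
            if b.work_start_s != a.rest_end_s:
                raise ValueError("stages must be contiguous and non-overlapping")

    @property
    def duration_s(self) -> float:
        return self.stages[-1].rest_end_s

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage(self, index: int) -> Stage:
        for s in self.stages:
            if s.index == index:
                return s
        raise KeyError(f"no stage with index {index}")

    def pct_wpeak(self, index: int) -> float:
        """Stage workload relative to Wpeak, in percent."""
        if self.wpeak_w is None:
            raise ValueError("wpeak_w is not set; call compute_wpeak first")
        return 100.0 * self.stage(index).workload_w / self.wpeak_w


def build_schedule(
    start_wkg: float,
    increment_wkg: float,
    n_stages: int,
    body_mass_kg: float,
    work_s: float = 300.0,
    rest_s: float = 60.0,
) -> StageSchedule:
    """Build the default ramp schedule: stage k at start + (k-1)·increment W·kg⁻¹.

    Wpeak defaults to the final stage's absolute workload (i.e. the final
    stage fully completed); use :func:`compute_wpeak` for partial completion.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if work_s <= 0 or rest_s < 0:
        raise ValueError("work_s must be > 0 and rest_s >= 0")
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    stages = []
    block = work_s + rest_s
    for k in range(1, n_stages + 1):
        wkg = start_wkg + (k - 1) * increment_wkg
        t0 = (k - 1) * block
        stages.append(
            Stage(
                index=k,
                workload_wkg=wkg,
                workload_w=wkg * body_mass_kg,
                work_start_s=t0,
                work_end_s=t0 + work_s,
                rest_end_s=t0 + block,
            )
        )
    sched = StageSchedule(stages=tuple(stages), body_mass_kg=body_mass_kg)
    sched.wpeak_w = stages[-1].workload_w
    return sched


def compute_wpeak(schedule: StageSchedule, completed_fraction_of_final: float) -> float:
    """Peak workload: last fully completed stage plus the completed fraction of
    the final (attempted) stage's increment.

    With fraction 1 this is the final stage's workload; with fraction 0 the
    previous stage's.  A single-stage schedule prorates from zero.
    """
    if not 0.0 <= completed_fraction_of_final <= 1.0:
        raise ValueError("completed fraction must be in [0, 1]")
    final_w = schedule.stages[-1].workload_w
    prev_w = schedule.stages[-2].workload_w if len(schedule.stages) >= 2 else 0.0
    return prev_w + completed_fraction_of_final * (final_w - prev_w)


def phase_at(schedule: StageSchedule, t: float) -> tuple[Phase, int]:
    """Map an absolute time to (phase, stage index), half-open [start, end).

    The single closing boundary t == schedule end is attributed to the final
    rest so the whole recording is covered.
    """
    if t < 0 or t > schedule.duration_s:
        raise ValueError(f"t={t} outside recording [0, {schedule.duration_s}]")
    for s in schedule.stages:
        if s.work_start_s <= t < s.work_end_s:
            return Phase.WORK, s.index
        if s.work_end_s <= t < s.rest_end_s:
            return Phase.REST, s.index
    return Phase.REST, schedule.stages[-1].index


def _schedule_from_mapping(cfg: dict) -> StageSchedule:
    if "stages" in cfg:
        stages = tuple(
            Stage(
                index=int(row["index"]),
                workload_wkg=float(row["watts"]) / float(cfg["body_mass_kg"]),
                workload_w=float(row["watts"]),
                work_start_s=float(row["start"]),
                work_end_s=float(row["end"]),
                rest_end_s=float(row["rest_end"]),
            )
            for row in cfg["stages"]
        )
        sched = StageSchedule(stages=stages, body_mass_kg=float(cfg["body_mass_kg"]))
        sched.wpeak_w = float(cfg.get("wpeak_w", stages[-1].workload_w))
        return sched
    sched = build_schedule(
        start_wkg=float(cfg.get("start_wkg", 1.0)),
        increment_wkg=float(cfg.get("increment_wkg", 0.5)),
        n_stages=int(cfg["n_stages"]),
        body_mass_kg=float(cfg["body_mass_kg"]),
        work_s=float(cfg.get("work_s", 300.0)),
        rest_s=float(cfg.get("rest_s", 60.0)),
    )
    frac = float(cfg.get("final_stage_completed_fraction", 1.0))
    sched.final_stage_completed_fraction = frac
    sched.wpeak_w = compute_wpeak(sched, frac)
    return sched


def load_schedule(source: str | Path | dict) -> StageSchedule:
    """Load a schedule from a YAML/JSON config mapping or file.

    Either ``n_stages`` (+ optional start/increment/work/rest) for the default
    ramp, or an explicit ``stages`` table (index, watts, start, end, rest_end).
    """
    if isinstance(source, dict):
        return _schedule_from_mapping(source)
    text = Path(source).read_text()
    cfg = yaml.safe_load(text) if not str(source).endswith(".json") else json.loads(text)
    return _schedule_from_mapping(cfg)
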