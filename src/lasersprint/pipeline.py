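"""End-to-end analysis: raw trace in, run report out.

Stages: calibration -> artifact repair -> start/end detection -> crop ->
differentiation/smoothing -> speed zones -> section splits -> step
segmentation -> symmetry -> report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional



from .errors import LaserSprintError, NoStepsDetected
from .gait import (
    GaitConfig,
    Step,
    StepEvent,
    SYMMETRY_VARIABLES,
    assign_sides,
    compute_step_metrics,
    detect_step_events,
    symmetry_index,
)
from .kinematics import (
    KinematicSeries,
    SectionSplit,
    SpeedZones,
    build_series,
    section_splits,
    segment_zones,
)
from .ldm_io import CalibratedTrace, MeasurementMeta, RawTrace, apply_calibration
from .preprocess import (
    ArtifactMask,
    SmoothingConfig,
    StartEndConfig,
    crop_bounds,
    detect_artifacts,
    detect_end,
    detect_start,
    moving_average,
    repair_artifacts,
)
from .stats_report import RunReport, build_report

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_trace"]


@dataclass
class AnalysisConfig:
    """Every knob of the analysis pipeline in one place."""

    start_end: StartEndConfig = field(
        default_factory=lambda: StartEndConfig(start_smooth_n=10)
    )
    smoothing: SmoothingConfig = field(
        default_factory=lambda: SmoothingConfig(
            overrides={"step_metrics": (9, 1)}
        )
    )
    gait: GaitConfig = field(default_factory=GaitConfig)
    vmax_phys: float = 13.0  # m/s, artifact speed threshold
    section_len: float = 10.0  # m
    total_distance: float = 100.0  # m

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisResult:
    """Everything one run analysis produced."""

    trace: CalibratedTrace  # cropped, repaired, time re-zeroed at start
    mask: ArtifactMask
    start_index: int  # within the cropped trace
    end_index: int
    series: KinematicSeries
    zones: SpeedZones  # indices relative to start_index
    splits: list[SectionSplit]
    events: list[StepEvent]
    steps: list[Step]
    symmetry: dict
    report: RunReport


def analyze_trace(
    raw: RawTrace,
    meta: Optional[MeasurementMeta] = None,
    config: Optional[AnalysisConfig] = None,
) -> AnalysisResult:
    """Run the full analysis pipeline on one raw trace."""
    meta = meta or MeasurementMeta()
    cfg = config or AnalysisConfig()

    calibrated = apply_calibration(raw, meta.calibration_distance_L1, meta)
    mask = detect_artifacts(calibrated, vmax_phys=cfg.vmax_phys)
    repaired = repair_artifacts(calibrated, mask)

    start = detect_start(repaired, cfg.start_end)
    end = detect_end(repaired, cfg.start_end)

    i0, i1 = crop_bounds(repaired, start, end, cfg.start_end)
    t = repaired.t[i0 : i1 + 1].copy()
    if cfg.start_end.rezero_time:
        t = t - repaired.t[start]
    x = repaired.x[i0 : i1 + 1].copy()
    trace = repaired.replace(t=t, x=x)
    s_idx = start - i0
    e_idx = end - i0

    series = build_series(trace.t, trace.x, cfg.smoothing)

    # zones over the detected run only (pad samples excluded)
    zones = segment_zones(
        series.v_smooth[s_idx : e_idx + 1], meta.max_speed_tolerance
    )

    try:
        splits = section_splits(
            series.t,
            series.x,
            series.v_smooth,
            section_len=cfg.section_len,
            total=cfg.total_distance,
            start_index=s_idx,
        )
    except LaserSprintError:
        splits = []

    # step detection on the lightly smoothed speed, run start to trace end
    v_detect = moving_average(
        series.v_raw, cfg.gait.detection_smoothing, cfg.gait.detection_passes
    )
    events: list[StepEvent] = []
    steps: list[Step] = []
    symmetry: dict = {}
    try:
        events = detect_step_events(
            series.t[s_idx:], v_detect[s_idx:], cfg.gait
        )
        steps = compute_step_metrics(events, series.t, series.x)
        steps = assign_sides(steps, meta.first_leg_on_start)
        if meta.first_leg_on_start != "unknown":
            for variable in SYMMETRY_VARIABLES:
                try:
                    symmetry[variable] = symmetry_index(steps, variable)
                except LaserSprintError:
                    pass
    except NoStepsDetected:
        pass

    report = build_report(
        meta=meta.to_dict(),
        series=series,
        zones=zones,
        splits=splits,
        steps=steps,
        symmetry=symmetry or None,
        mask=mask,
        configs=cfg.to_dict(),
        run_offset=s_idx,
        smoothing=cfg.smoothing,
    )
    return AnalysisResult(
        trace=trace,
        mask=mask,
        start_index=s_idx,
        end_index=e_idx,
        series=series,
        zones=zones,
        splits=splits,
        events=events,
        steps=steps,
        symmetry=symmetry,
        report=report,
    )
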