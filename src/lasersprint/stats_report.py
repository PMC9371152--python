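"""Descriptive statistics, correlation and the machine-readable run report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import CorrelationUndefined, ReportError, StatsError
from .gait import Step, SymmetryReport, steps_to_frame
from .kinematics import KinematicSeries, SectionSplit, SpeedZones, splits_to_frame
from .preprocess import ArtifactMask, SmoothingConfig, moving_average

__all__ = [
    "DescriptiveStats",
    "RunReport",
    "descriptive_stats",
    "pearson_corr",
    "build_report",
]


@dataclass
class DescriptiveStats:
    """Summary statistics of one variable.

    ``sd`` is the sample standard deviation (divisor n-1); ``kurtosis`` is
    excess kurtosis (0 for a normal distribution).  Skewness/kurtosis are
    ``None`` when undefined (n < 3 / n < 4 or zero spread); for a single
    value ``sd`` is reported as 0 with ``degenerate=True``.
    """

    n: int
    mean: float
    median: float
    mode: float
    minimum: float
    maximum: float
    sd: float
    skewness: Optional[float]
    kurtosis: Optional[float]
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def descriptive_stats(values, mode_precision: int = 2) -> DescriptiveStats:
    """Mean, median, mode, min, max, sd, skewness and excess kurtosis.

    The mode of continuous data is the most frequent value after rounding to
    ``mode_precision`` decimals, smallest value on ties.  Skewness and
    kurtosis use the population-moment formulas
    ``g1 = m3 / m2^1.5`` and ``g2 = m4 / m2^2 - 3``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("empty input")
    if not np.all(np.isfinite(v)):
        raise StatsError("non-finite values")
    n = int(v.size)

    rounded = np.round(v, mode_precision)
    uniq, counts = np.unique(rounded, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique sorts -> smallest tie

    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0

    dev = v - mean
    m2 = float(np.mean(dev**2))
    skew = kurt = None
    if m2 > 0 and m2**1.5 > 0:  # m2**1.5 can underflow for tiny spreads
        if n >= 3:
            skew = float(np.mean(dev**3) / m2**1.5)
        if n >= 4 and m2**2 > 0:
            kurt = float(np.mean(dev**4) / m2**2 - 3.0)

    return DescriptiveStats(
        n=n,
        mean=mean,
        median=float(np.median(v)),
        mode=mode,
        minimum=float(np.min(v)),
        maximum=float(np.max(v)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        degenerate=(n == 1),
    )


def pearson_corr(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError(f"length mismatch ({x.size} vs {y.size})")
    if x.size < 3:
        raise StatsError("need at least 3 pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        raise CorrelationUndefined("zero variance in one argument")
    r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    return max(-1.0, min(1.0, r))


#: Step variables summarized in the report's descriptive-stats section.
_STEP_STAT_COLUMNS = (
    "support_s",
    "flight_s",
    "step_s",
    "length_m",
    "frequency_hz",
    "mean_speed",
)


@dataclass
class RunReport:
    """All tables of one analyzed run plus processing provenance."""

    meta: dict
    zones: dict
    splits: pd.DataFrame
    steps: pd.DataFrame
    symmetry: dict
    step_stats: dict
    provenance: dict
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "zones": self.zones,
            "splits": self.splits.to_dict(orient="records"),
            "steps": self.steps.to_dict(orient="records"),
            "symmetry": self.symmetry,
            "step_stats": self.step_stats,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, allow_nan=True)

    def write_bundle(self, outdir, mask: Optional[ArtifactMask] = None) -> None:
        """Write report.json plus the CSV/JSON side tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.splits.to_csv(outdir / "splits.csv", index=False)
        self.steps.to_csv(outdir / "steps.csv", index=False)
        pd.DataFrame([self.zones]).to_json(
            outdir / "zones.json", orient="records", indent=2
        )
        (outdir / "symmetry.json").write_text(
            json.dumps(self.symmetry, indent=2)
        )
        if mask is not None:
            mask.to_csv(outdir / "mask.csv")


def _zone_summary(series: KinematicSeries, zones: SpeedZones, offset: int) -> dict:
    """Durations, distances and speeds per zone, in run coordinates."""
    out: dict = {
        "tolerance": zones.tolerance,
        "v_max": zones.v_max,
        "t_vmax": float(series.t[offset + zones.i_vmax]),
        "x_vmax": float(series.x[offset + zones.i_vmax]),
    }
    for name, (i0, i1) in (
        ("ascending", zones.ascending),
        ("maintenance", zones.maintenance),
        ("descending", zones.descending),
    ):
        if i1 <= i0:
            out[name] = None
            continue
        a, b = offset + i0, offset + i1 - 1
        v = series.v_smooth[a : b + 1]
        out[name] = {
            "t_from": float(series.t[a]),
            "t_to": float(series.t[b]),
            "x_from": float(series.x[a]),
            "x_to": float(series.x[b]),
            "duration_s": float(series.t[b] - series.t[a]),
            "distance_m": float(series.x[b] - series.x[a]),
            "mean_speed": float(np.mean(v)),
            "max_speed": float(np.max(v)),
        }
    return out


def build_report(
    meta: Optional[dict],
    series: Optional[KinematicSeries],
    zones: Optional[SpeedZones],
    splits: Optional[list[SectionSplit]],
    steps: Optional[list[Step]],
    symmetry: Optional[dict[str, SymmetryReport]],
    mask: Optional[ArtifactMask] = None,
    configs: Optional[dict] = None,
    run_offset: int = 0,
    smoothing: Optional[SmoothingConfig] = None,
) -> RunReport:
    """Assemble the per-run report from the pipeline stage outputs.

    ``series`` and ``zones`` are mandatory; steps/symmetry sections are
    omitted (with a recorded warning) when unavailable.  When a smoothing
    config is given, the per-step series additionally carry a smoothed
    variant (the ``step_metrics`` smoothing setting), the per-step
    counterpart of the smoothed bold curves of the source method.
    """
    if series is None or zones is None:
        raise ReportError("kinematics stage output is mandatory")

    warnings: list[str] = []
    steps_frame = steps_to_frame(steps) if steps else pd.DataFrame()
    if not steps:
        warnings.append("no steps detected; step tables empty")
    elif smoothing is not None:
        n_sm, m_sm = smoothing.for_variable("step_metrics")
        for col in ("step_s", "length_m", "frequency_hz"):
            steps_frame[col + "_smooth"] = moving_average(
                steps_frame[col].to_numpy(), min(n_sm, len(steps_frame)), m_sm
            )

    sym_dict: dict = {}
    if symmetry:
        sym_dict = {k: r.as_dict() for k, r in symmetry.items()}
    else:
        warnings.append("symmetry unavailable (sides unknown or one-sided)")

    step_stats: dict = {}
    if len(steps_frame):
        for col in _STEP_STAT_COLUMNS:
            step_stats[col] = descriptive_stats(
                steps_frame[col].to_numpy()
            ).as_dict()

    provenance = {
        "software_version": _pkg_version,
        "configs": configs or {},
        "artifact_segments": mask.n_segments if mask is not None else 0,
        "artifact_samples": mask.n_flagged if mask is not None else 0,
    }

    return RunReport(
        meta=meta or {},
        zones=_zone_summary(series, zones, run_offset),
        splits=splits_to_frame(splits or []),
        steps=steps_frame,
        symmetry=sym_dict,
        step_stats=step_stats,
        provenance=provenance,
        warnings=warnings,
    )
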