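"""Velocity, acceleration, speed zones and fixed-length section splits.

Differentiation uses plain central differences on the actual sample times,
``v_i = (x_{i+1} - x_{i-1}) / (t_{i+1} - t_{i-1})``, with one-sided
differences at the two ends; acceleration applies the same stencil to the
velocity.  The run is segmented into three contiguous speed zones
(ascending / maintenance of the maximum / descending) where maintenance is
the first-to-last span of samples within a relative tolerance (default 2%)
of the peak of the smoothed speed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ComputeError
from .preprocess import SmoothingConfig, moving_average

__all__ = [
    "KinematicSeries",
    "SpeedZones",
    "SectionSplit",
    "compute_velocity",
    "compute_acceleration",
    "build_series",
    "segment_zones",
    "section_splits",
    "splits_to_frame",
]


def _central_difference(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ComputeError("need at least 3 samples to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ComputeError("sample times must be strictly increasing")
    out = np.empty_like(y)
    out[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    out[0] = (y[1] - y[0]) / (t[1] - t[0])
    out[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return out


def compute_velocity(t, x) -> np.ndarray:
    """Central-difference speed from displacement, m/s."""
    return _central_difference(t, x)


def compute_acceleration(t, v) -> np.ndarray:
    """Central-difference acceleration from speed, m/s^2."""
    return _central_difference(t, v)


@dataclass
class KinematicSeries:
    """Aligned time/displacement/speed/acceleration arrays."""

    t: np.ndarray
    x: np.ndarray
    v_raw: np.ndarray
    v_smooth: np.ndarray
    a_raw: np.ndarray
    a_smooth: np.ndarray
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("x", "v_raw", "v_smooth", "a_raw", "a_smooth"):
            if getattr(self, name).size != n:
                raise ComputeError(f"{name} length differs from t")

    @property
    def n(self) -> int:
        return int(self.t.size)


def build_series(
    t, x, smoothing: Optional[SmoothingConfig] = None
) -> KinematicSeries:
    """Differentiate displacement twice and attach smoothed variants.

    ``v_smooth`` uses the ``velocity`` smoothing setting (default n=10, the
    0.1 s window at 100 Hz); ``a_smooth`` differentiates the smoothed speed
    and smooths again with the ``acceleration`` setting.
    """
    smoothing = smoothing or SmoothingConfig()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    v_raw = compute_velocity(t, x)
    n_v, m_v = smoothing.for_variable("velocity")
    v_smooth = moving_average(v_raw, n_v, m_v)
    a_raw = compute_acceleration(t, v_raw)
    n_a, m_a = smoothing.for_variable("acceleration")
    a_smooth = moving_average(compute_acceleration(t, v_smooth), n_a, m_a)
    return KinematicSeries(
        t=t, x=x, v_raw=v_raw, v_smooth=v_smooth,
        a_raw=a_raw, a_smooth=a_smooth, smoothing=smoothing,
    )


@dataclass
class SpeedZones:
    """Three contiguous index ranges partitioning ``[0, n)``.

    ``ascending`` and ``descending`` may be empty; ``maintenance`` always
    contains the index of the peak smoothed speed.
    """

    ascending: tuple[int, int]
    maintenance: tuple[int, int]
    descending: tuple[int, int]
    tolerance: float
    v_max: float
    i_vmax: int

    def as_dict(self) -> dict:
        return {
            "ascending": list(self.ascending),
            "maintenance": list(self.maintenance),
            "descending": list(self.descending),
            "tolerance": self.tolerance,
            "v_max": self.v_max,
            "i_vmax": self.i_vmax,
        }


def segment_zones(v_smooth, tolerance: float = 0.02) -> SpeedZones:
    """Split the run into ascending / maintenance / descending speed zones.

    Maintenance spans from the first to the last sample with
    ``v >= (1 - tolerance) * v_max``; interior dips below the threshold stay
    inside maintenance so the three zones are contiguous.
    """
    v = np.asarray(v_smooth, dtype=float)
    if v.size == 0:
        raise ComputeError("empty speed array")
    if not (0.0 < tolerance < 0.5):
        raise ComputeError(f"tolerance {tolerance} outside (0, 0.5)")
    v_max = float(np.max(v))
    i_vmax = int(np.argmax(v))  # first occurrence on ties
    threshold = (1.0 - tolerance) * v_max
    within = np.flatnonzero(v >= threshold)
    first, last = int(within[0]), int(within[-1])
    return SpeedZones(
        ascending=(0, first),
        maintenance=(first, last + 1),
        descending=(last + 1, int(v.size)),
        tolerance=float(tolerance),
        v_max=v_max,
        i_vmax=i_vmax,
    )


@dataclass
class SectionSplit:
    """Timing of one fixed-length section of the race distance."""

    section_from: float  # m
    section_to: float  # m
    split_time: float  # s
    cumulative_time: float  # s, from the 0 m crossing
    mean_speed: float  # m/s
    max_speed: float  # m/s, max of smoothed speed inside the section
    partial: bool = False


def _crossing_time(
    t: np.ndarray, x: np.ndarray, boundary: float, search_from: int
) -> Optional[float]:
    """Time of the first upward crossing of ``boundary``, interpolated."""
    over = x[search_from:] > boundary
    if not over.any():
        return None
    i = search_from + int(np.argmax(over))
    if i == 0 or x[i] == x[i - 1]:
        return float(t[i])
    frac = (boundary - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _start_line_time(
    t: np.ndarray, x: np.ndarray, start_index: int, fit_window: float = 0.4
) -> Optional[float]:
    """Start-line (x = 0) crossing by quadratic back-extrapolation.

    The early displacement of a static-start sprint is smooth and slowly
    curving, so a low-order polynomial fitted just after the detected
    start locates the true x=0 crossing far more precisely than a noisy
    first-crossing scan: threshold-based start detection fires only once
    the displacement clears the noise band, i.e. systematically late.
    A cubic absorbs the decay of the initial acceleration.
    """
    if start_index >= t.size - 7:
        return _crossing_time(t, x, 0.0, start_index)
    dt = float(np.median(np.diff(t)))
    n_fit = max(7, int(round(fit_window / dt)))
    win = slice(start_index, min(t.size, start_index + n_fit))
    z = t[win] - t[start_index]
    c = np.polyfit(z, x[win], 3)
    roots = np.roots(c)
    roots = roots[np.isreal(roots)].real
    roots = roots[(roots >= -3.0 * fit_window) & (roots <= fit_window)]
    if roots.size == 0:
        return _crossing_time(t, x, 0.0, start_index)
    z0 = float(roots[np.argmin(np.abs(roots))])
    return float(t[start_index] + z0)


def section_splits(
    t,
    x,
    v_smooth,
    section_len: float = 10.0,
    total: float = 100.0,
    start_index: int = 0,
) -> list[SectionSplit]:
    """Split times over consecutive ``section_len`` sections of the run.

    Boundary crossing times are linearly interpolated between the bracketing
    samples; the scan begins at ``start_index`` (the detected start) so that
    pre-start noise around x=0 cannot trigger the 0 m boundary early.  An
    incomplete final section is reported with ``partial=True`` using the
    farthest point reached.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v_smooth, dtype=float)
    if section_len <= 0 or total <= 0:
        raise ComputeError("section_len and total must be > 0")
    if np.nanmax(x) < section_len:
        raise ComputeError(
            f"trace shorter than one section ({section_len} m)"
        )

    n_sections = int(np.floor(total / section_len + 1e-9))
    boundaries = [k * section_len for k in range(n_sections + 1)]
    times: list[Optional[float]] = [_start_line_time(t, x, start_index)]
    for b in boundaries[1:]:
        times.append(_crossing_time(t, x, b, start_index))

    splits: list[SectionSplit] = []
    t0 = times[0]
    if t0 is None:
        raise ComputeError("run never crosses the 0 m boundary")
    cumulative = 0.0
    for k in range(n_sections):
        ta, tb = times[k], times[k + 1]
        if ta is None:
            break
        if tb is None:
            # partial final section up to the farthest point reached
            i_far = int(np.nanargmax(x))
            reached = float(x[i_far]) - boundaries[k]
            if reached <= 0:
                break
            dt_sec = float(t[i_far]) - ta
            if dt_sec <= 0:
                break
            in_sec = (t >= ta) & (t <= t[i_far])
            splits.append(
                SectionSplit(
                    section_from=boundaries[k],
                    section_to=boundaries[k] + reached,
                    split_time=dt_sec,
                    cumulative_time=cumulative + dt_sec,
                    mean_speed=reached / dt_sec,
                    max_speed=float(np.max(v[in_sec])) if in_sec.any() else np.nan,
                    partial=True,
                )
            )
            break
        dt_sec = tb - ta
        cumulative += dt_sec
        in_sec = (t >= ta) & (t <= tb)
        splits.append(
            SectionSplit(
                section_from=boundaries[k],
                section_to=boundaries[k + 1],
                split_time=dt_sec,
                cumulative_time=cumulative,
                mean_speed=section_len / dt_sec,
                max_speed=float(np.max(v[in_sec])) if in_sec.any() else np.nan,
            )
        )
    return splits


def splits_to_frame(splits: list[SectionSplit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "section_from_m": [s.section_from for s in splits],
            "section_to_m": [s.section_to for s in splits],
            "split_s": [s.split_time for s in splits],
            "cumulative_s": [s.cumulative_time for s in splits],
            "mean_speed": [s.mean_speed for s in splits],
            "max_speed": [s.max_speed for s in splits],
            "partial": [s.partial for s in splits],
        }
    )
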