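"""Artifact repair, start/end detection, cropping and moving-average smoothing.

The sprint start is found with a threshold rule: the displacement must rise
and *hold* above ``mean_pre + max(k_sd * sd_pre, min_threshold)``, where the
pre-start statistics come from the first ``pre_window`` seconds of signal.
The end point is a fixed number of samples after the displacement first
exceeds ``end_distance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, EndNotReached, NoStartDetected, RepairError
from .ldm_io import CalibratedTrace

__all__ = [
    "SmoothingConfig",
    "StartEndConfig",
    "ArtifactMask",
    "moving_average",
    "detect_artifacts",
    "repair_artifacts",
    "detect_start",
    "detect_end",
    "crop",
]


@dataclass
class SmoothingConfig:
    """Moving-average parameters, optionally overridden per variable.

    ``overrides`` maps a variable name (``displacement``, ``velocity``,
    ``acceleration``, ``step_metrics``) to a ``(window_n, passes_m)`` pair.
    """

    window_n: int = 10
    passes_m: int = 1
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise ConfigError("window_n must be >= 1")
        if self.passes_m < 1:
            raise ConfigError("passes_m must be >= 1")

    def for_variable(self, variable: str) -> tuple[int, int]:
        n, m = self.overrides.get(variable, (self.window_n, self.passes_m))
        if n < 1 or m < 1:
            raise ConfigError(f"invalid smoothing override for {variable!r}")
        return int(n), int(m)


@dataclass
class StartEndConfig:
    """Parameters of the start/end threshold rules and the crop."""

    k_sd: float = 2.0
    pre_window: float = 1.0  # s of assumed pre-start signal
    min_threshold: float = 0.01  # m floor for the threshold
    hold: float = 0.1  # s the signal must stay above threshold
    end_distance: float = 60.0  # m
    end_extra_points: int = 50  # samples appended after the end crossing
    crop_pad: float = 1.0  # s kept before start / after end
    rezero_time: bool = True  # shift t so the detected start is t=0
    start_smooth_n: int = 1  # pre-smoothing applied inside detect_start

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ConfigError("k_sd must be > 0")
        if self.end_extra_points < 0:
            raise ConfigError("end_extra_points must be >= 0")
        if self.crop_pad < 0:
            raise ConfigError("crop_pad must be >= 0")
        if self.start_smooth_n < 1:
            raise ConfigError("start_smooth_n must be >= 1")


@dataclass
class ArtifactMask:
    """Disjoint, sorted half-open index ranges of corrupted samples."""

    segments: list[tuple[int, int]] = field(default_factory=list)
    causes: list[str] = field(default_factory=list)  # dropout | spike | edge

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.causes):
            raise ConfigError("segments and causes must have equal length")
        prev_end = 0
        for (i0, i1), cause in zip(self.segments, self.causes):
            if i0 >= i1:
                raise ConfigError(f"empty or inverted segment ({i0}, {i1})")
            if i0 < prev_end:
                raise ConfigError("segments overlap or are unsorted")
            if cause not in ("dropout", "spike", "edge"):
                raise ConfigError(f"unknown cause {cause!r}")
            prev_end = i1

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_flagged(self) -> int:
        return sum(i1 - i0 for i0, i1 in self.segments)

    def indices(self, n: int) -> np.ndarray:
        """Boolean mask of length ``n`` with flagged samples True."""
        flag = np.zeros(n, dtype=bool)
        for i0, i1 in self.segments:
            if i1 > n:
                raise ConfigError("segment exceeds trace bounds")
            flag[i0:i1] = True
        return flag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_index": [s[0] for s in self.segments],
                "end_index": [s[1] for s in self.segments],
                "cause": self.causes,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def moving_average(y, window_n: int, passes_m: int = 1) -> np.ndarray:
    """Centered moving average with edge-truncated windows.

    The window around index ``i`` covers ``[i - (n-1)//2, i + n//2]``,
    clipped to the array bounds, so the output has the same length as the
    input.  The filter is applied ``passes_m`` times.
    """
    if window_n < 1:
        raise ConfigError("window_n must be >= 1")
    if passes_m < 1:
        raise ConfigError("passes_m must be >= 1")
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ConfigError("empty array")
    if window_n == 1:
        return y.copy()
    left = (window_n - 1) // 2
    right = window_n // 2
    n = y.size
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    out = y
    for _ in range(passes_m):
        csum = np.concatenate(([0.0], np.cumsum(out)))
        out = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _runs_from_flags(flag: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of consecutive True values."""
    if not flag.any():
        return []
    padded = np.concatenate(([False], flag, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_artifacts(
    trace: CalibratedTrace, vmax_phys: float = 13.0
) -> ArtifactMask:
    """Flag dropouts (non-finite samples) and spikes.

    A sample is a spike when the speed implied from the last clean sample,
    ``|dx/dt|``, exceeds ``vmax_phys`` — faster than any human sprinter, so
    the beam must have caught something else.  The reference stays at the
    last clean sample so that multi-sample excursions are flagged in full.
    """
    x, t = trace.x, trace.t
    n = x.size
    finite = np.isfinite(x)
    flagged = ~finite
    cause = np.array(["dropout"] * n, dtype=object)

    fin_idx = np.flatnonzero(finite)
    if fin_idx.size >= 2:
        ref = fin_idx[0]
        for j in fin_idx[1:]:
            speed = abs(x[j] - x[ref]) / (t[j] - t[ref])
            if speed > vmax_phys:
                flagged[j] = True
                cause[j] = "spike"
            else:
                ref = j

    segments, causes = [], []
    for i0, i1 in _runs_from_flags(flagged):
        if i0 == 0 or i1 == n:
            seg_cause = "edge"
        else:
            seg = cause[i0:i1]
            seg_cause = "spike" if np.all(seg == "spike") else "dropout"
        segments.append((int(i0), int(i1)))
        causes.append(seg_cause)
    return ArtifactMask(segments=segments, causes=causes)


def repair_artifacts(
    trace: CalibratedTrace, mask: ArtifactMask
) -> CalibratedTrace:
    """Repair flagged samples; crop segments touching the trace ends.

    Interior segments are replaced by linear interpolation in time between
    the nearest clean neighbours.  Unflagged samples are returned
    bit-identical.
    """
    n = trace.n
    flagged = mask.indices(n)
    if flagged.all():
        raise RepairError("artifact mask covers the entire trace")
    if not flagged.any():
        return trace

    keep_lo = 0
    keep_hi = n
    for (i0, i1), _ in zip(mask.segments, mask.causes):
        if i0 == 0:
            keep_lo = max(keep_lo, i1)
        if i1 == n:
            keep_hi = min(keep_hi, i0)
    if keep_lo >= keep_hi:
        raise RepairError("edge artifacts leave no clean interior")

    t = trace.t[keep_lo:keep_hi]
    x = trace.x[keep_lo:keep_hi].copy()
    flag = flagged[keep_lo:keep_hi]
    clean = ~flag
    if clean.sum() < 2:
        raise RepairError("fewer than two clean samples to interpolate from")
    x[flag] = np.interp(t[flag], t[clean], x[clean])
    return trace.replace(t=t, x=x)


def _rate(trace: CalibratedTrace) -> float:
    return 1.0 / trace.median_dt


def detect_start(trace: CalibratedTrace, cfg: StartEndConfig) -> int:
    """First index where x rises and holds above the pre-start threshold.

    The threshold is ``mean_pre + max(k_sd * sd_pre, min_threshold)`` with
    the pre-start statistics taken over the first ``pre_window`` seconds;
    "holds" means every sample in the following ``hold`` seconds stays above
    it.  ``start_smooth_n > 1`` applies a moving average before scanning
    (recommended for noisy field data).
    """
    rate = _rate(trace)
    x = trace.x
    if cfg.start_smooth_n > 1:
        x = moving_average(x, cfg.start_smooth_n)
    n_pre = int(round(cfg.pre_window * rate))
    if n_pre < 2:
        raise ConfigError("pre_window shorter than two samples")
    if n_pre >= trace.n:
        raise ConfigError("pre_window longer than the trace")
    pre = x[:n_pre]
    mean_pre = float(np.mean(pre))
    sd_pre = float(np.std(pre))
    threshold = mean_pre + max(cfg.k_sd * sd_pre, cfg.min_threshold)

    hold_n = max(1, int(round(cfg.hold * rate)))
    above = x > threshold
    if above.size < hold_n:
        raise NoStartDetected("trace shorter than the hold window")
    # rolling all-true over hold_n samples
    csum = np.concatenate(([0], np.cumsum(above.astype(np.int64))))
    window_sum = csum[hold_n:] - csum[:-hold_n]
    holds = np.flatnonzero(window_sum == hold_n)
    if holds.size == 0:
        raise NoStartDetected(
            f"displacement never held above {threshold:.4f} m "
            f"for {hold_n} samples"
        )
    return int(holds[0])


def detect_end(trace: CalibratedTrace, cfg: StartEndConfig) -> int:
    """``end_extra_points`` samples after x first exceeds ``end_distance``."""
    over = trace.x > cfg.end_distance
    if not over.any():
        raise EndNotReached(
            f"displacement never exceeds {cfg.end_distance} m "
            f"(max {np.nanmax(trace.x):.2f} m)"
        )
    first = int(np.argmax(over))
    return min(first + cfg.end_extra_points, trace.n - 1)


def crop(
    trace: CalibratedTrace,
    start: int,
    end: int,
    cfg: Optional[StartEndConfig] = None,
) -> CalibratedTrace:
    """Restrict the trace to the detected run plus a padding window."""
    cfg = cfg or StartEndConfig()
    if start >= end:
        raise ConfigError(f"start ({start}) must be < end ({end})")
    if start < 0 or end >= trace.n:
        raise ConfigError("start/end outside trace bounds")
    pad = int(round(cfg.crop_pad * _rate(trace)))
    i0 = max(0, start - pad)
    i1 = min(trace.n - 1, end + pad)
    t = trace.t[i0 : i1 + 1].copy()
    if cfg.rezero_time:
        t = t - trace.t[start]
    return trace.replace(t=t, x=trace.x[i0 : i1 + 1].copy())


def crop_bounds(
    trace: CalibratedTrace, start: int, end: int, cfg: StartEndConfig
) -> tuple[int, int]:
    """Index range ``[i0, i1]`` that :func:`crop` keeps (inclusive)."""
    pad = int(round(cfg.crop_pad * _rate(trace)))
    return max(0, start - pad), min(trace.n - 1, end + pad)
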