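"""Step segmentation from the within-step velocity oscillation.

The running speed of the tracked lumbar point oscillates once per step: it
falls during flight (no propulsion) and rises again during ground contact.
Local minima of a lightly smoothed speed curve therefore mark touchdowns,
local maxima mark toe-offs.  Consecutive touchdowns delimit one step;
the toe-off between them splits it into support and flight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    ConfigError,
    NoStepsDetected,
    StepStructureError,
    SymmetryUnavailable,
)
from .preprocess import moving_average

__all__ = [
    "GaitConfig",
    "StepEvent",
    "Step",
    "SymmetryReport",
    "detect_step_events",
    "compute_step_metrics",
    "assign_sides",
    "symmetry_index",
    "steps_to_frame",
    "SYMMETRY_VARIABLES",
]

logger = logging.getLogger(__name__)

#: Step variables a symmetry report can be computed for.
SYMMETRY_VARIABLES = (
    "speed",
    "step_length",
    "support_time",
    "flight_time",
    "step_frequency",
    "step_time",
)

_VARIABLE_ATTR = {
    "speed": "mean_speed",
    "step_length": "step_length",
    "support_time": "support_time",
    "flight_time": "flight_time",
    "step_frequency": "step_frequency",
    "step_time": "step_time",
}


@dataclass
class GaitConfig:
    """Plausibility bounds and detection tuning for step segmentation.

    ``min_step_time``/``max_step_time`` bound physiologically possible
    sprint step times (step frequency roughly 1.7-6.7 Hz);
    ``detection_smoothing``/``detection_passes`` control the moving average
    applied to the raw speed before extremum picking — small enough to keep
    the within-step fluctuation that the analysis smoothing removes.
    ``boundary`` chooses the step convention: ``touchdown`` (touchdown to
    contralateral touchdown, the default) or ``toeoff``.
    """

    min_step_time: float = 0.15  # s
    max_step_time: float = 0.60  # s
    min_prominence: float = 0.05  # m/s
    detection_smoothing: int = 3  # samples
    detection_passes: int = 1
    detrend_s: float = 0.45  # s, slow-trend window removed before picking
    refine_subsample: bool = True  # parabolic extremum refinement
    refine_halfwidth: int = 1  # samples each side of the extremum to fit
    periodic_prune: bool = False  # periodicity-based event validation
    boundary: str = "touchdown"  # touchdown | toeoff

    def __post_init__(self) -> None:
        if not (0.0 < self.min_step_time < self.max_step_time):
            raise ConfigError("need 0 < min_step_time < max_step_time")
        if self.min_prominence < 0:
            raise ConfigError("min_prominence must be >= 0")
        if self.detection_smoothing < 1 or self.detection_passes < 1:
            raise ConfigError("detection smoothing parameters must be >= 1")
        if self.detrend_s <= 0:
            raise ConfigError("detrend_s must be > 0")
        if self.refine_halfwidth < 1:
            raise ConfigError("refine_halfwidth must be >= 1")
        if self.boundary not in ("touchdown", "toeoff"):
            raise ConfigError("boundary must be 'touchdown' or 'toeoff'")


@dataclass
class StepEvent:
    """One gait event: a touchdown (speed minimum) or toe-off (maximum)."""

    index: int
    time: float
    kind: str  # touchdown | toeoff

    def __post_init__(self) -> None:
        if self.kind not in ("touchdown", "toeoff"):
            raise ConfigError(f"unknown event kind {self.kind!r}")


@dataclass
class Step:
    """One running step (touchdown to contralateral touchdown)."""

    ordinal: int
    side: str  # L | R | unknown
    t_touchdown: float
    t_toeoff: float
    t_next_touchdown: float
    support_time: float
    flight_time: float
    step_time: float
    step_length: float
    step_frequency: float
    mean_speed: float
    boundary_step: bool = False  # first/last step of the run


@dataclass
class SymmetryReport:
    variable: str
    mean_left: float
    mean_right: float
    symmetry_index: float  # percent, >= 0

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "mean_left": self.mean_left,
            "mean_right": self.mean_right,
            "symmetry_index": self.symmetry_index,
        }


def _refine_time(
    t: np.ndarray, v: np.ndarray, i: int, halfwidth: int = 1
) -> float:
    """Sub-sample extremum location by a least-squares parabola fit."""
    a = max(0, i - halfwidth)
    b = min(v.size, i + halfwidth + 1)
    if b - a < 3:
        return float(t[i])
    xs = t[a:b] - t[i]
    c2, c1, _ = np.polyfit(xs, v[a:b], 2)
    if c2 == 0:
        return float(t[i])
    dt = float(np.median(np.diff(t)))
    delta = float(np.clip(-c1 / (2.0 * c2), -2.0 * dt, 2.0 * dt))
    return float(t[i] + delta)


def _alternate(events: list[StepEvent], v: np.ndarray) -> list[StepEvent]:
    """Enforce strict touchdown/toe-off alternation.

    Among consecutive same-kind events the more extreme one is kept
    (lower speed for touchdowns, higher for toe-offs).
    """
    out: list[StepEvent] = []
    for ev in events:
        if out and out[-1].kind == ev.kind:
            prev = out[-1]
            if ev.kind == "touchdown":
                better = ev if v[ev.index] < v[prev.index] else prev
            else:
                better = ev if v[ev.index] > v[prev.index] else prev
            out[-1] = better
        else:
            out.append(ev)
    return out


def _periodic_walk(
    r: np.ndarray,
    td_idx: list[int],
    dt: float,
    cfg: GaitConfig,
) -> list[int]:
    """Validate/extend the touchdown chain using step periodicity.

    From the strongest detected touchdown, walk outwards in steps of the
    locally estimated period, accepting the deepest residual minimum inside
    a +-30% search window while its depth stays above a fraction of the
    established step depth.  Recovers minima the peak picker suppressed and
    rejects isolated noise extrema outside the oscillating region.
    """
    if len(td_idx) < 3:
        return td_idx
    td = np.asarray(td_idx)
    # trend-removal edge effects corrupt the residual near the slice
    # boundaries: keep anchor and depth reference away from them
    guard = int(round(cfg.detrend_s / dt))
    interior = td[(td > guard) & (td < r.size - guard)]
    if interior.size < 3:
        interior = td
    depths = -r[interior]
    order = np.argsort(depths)[::-1]
    strong = np.sort(interior[order[: max(3, interior.size // 2)]])
    depth_ref = float(np.median(-r[strong]))
    anchor = int(interior[int(np.argmax(depths))])

    # step period from the autocorrelation of the interior residual: far
    # more robust under noise than the median inter-minimum interval
    core = r[guard : r.size - guard]
    if core.size < 4 * int(cfg.max_step_time / dt):
        return td_idx
    core = core - core.mean()
    lag_min = max(2, int(round(cfg.min_step_time / dt)))
    lag_max = min(core.size - 2, int(round(cfg.max_step_time / dt)))
    acf = np.array(
        [
            float(np.dot(core[:-lag], core[lag:]) / (core.size - lag))
            for lag in range(lag_min, lag_max + 1)
        ]
    )
    # the autocorrelation peaks equally at every multiple of the period:
    # take the smallest local maximum close to the global one
    k = int(np.argmax(acf))
    peaks_k, _ = find_peaks(acf, height=0.7 * acf[k])
    if peaks_k.size:
        k = int(peaks_k[0])

    def _refined_lag(kk: int) -> float:
        lag = float(lag_min + kk)
        if 0 < kk < acf.size - 1:
            denom = acf[kk - 1] - 2.0 * acf[kk] + acf[kk + 1]
            if denom != 0:
                lag += float(
                    np.clip(
                        0.5 * (acf[kk - 1] - acf[kk + 1]) / denom, -0.5, 0.5
                    )
                )
        return lag

    best_lag = _refined_lag(k)
    # the peak at twice the period has twice the relative precision; use it
    # when it lies inside the searched lag range
    k2 = int(round(2.0 * best_lag)) - lag_min
    if 2 <= k2 < acf.size - 2:
        w2 = max(2, int(round(0.2 * best_lag)))
        lo2, hi2 = max(0, k2 - w2), min(acf.size, k2 + w2 + 1)
        k2 = lo2 + int(np.argmax(acf[lo2:hi2]))
        lag2 = _refined_lag(k2)
        if abs(lag2 / 2.0 - best_lag) < 0.2 * best_lag:
            best_lag = lag2 / 2.0
    period = best_lag * dt

    p_samp = period / dt

    # robust phase: fit touchdown index ~ phase + k * period over the
    # strong minima (cycle numbers assigned relative to the anchor), which
    # pins the whole grid without cumulative drift.  Iterate the fit: the
    # initial autocorrelation period is only good to ~1 sample per cycle,
    # so distant minima may first get the wrong cycle number.
    lo_p = cfg.min_step_time / dt
    hi_p = cfg.max_step_time / dt
    phase = float(anchor)
    sel = strong.astype(float)
    # cycle numbers by chaining consecutive gaps: local rounding errors do
    # not accumulate with distance the way a global division would
    k_sel = np.concatenate(
        ([0.0], np.cumsum(np.round(np.diff(sel) / p_samp)))
    )
    for _ in range(3):
        if np.unique(k_sel).size < 2:
            break
        slope, intercept = np.polyfit(k_sel, sel, 1)
        if not (lo_p <= slope <= hi_p):
            break
        resid = np.abs(sel - (intercept + slope * k_sel))
        keep = resid <= 0.25 * slope
        if keep.sum() >= 3:
            sel, k_sel = sel[keep], k_sel[keep]
        p_samp, phase = float(slope), float(intercept)
        k_sel = np.round((sel - phase) / p_samp)

    k_min = int(np.ceil((1 - phase) / p_samp))
    k_max = int(np.floor((r.size - 2 - phase) / p_samp))
    if k_max - k_min < 1:
        return td_idx
    grid = [int(round(phase + k * p_samp)) for k in range(k_min, k_max + 1)]

    # localized touchdown candidates: residual minimum near each grid node
    snap = max(2, int(round(0.2 * p_samp)))
    nodes = []
    for g in grid:
        lo = max(0, g - snap)
        hi = min(r.size, g + snap + 1)
        nodes.append(lo + int(np.argmin(r[lo:hi])))

    # fixed-phase matched evidence per cycle: projection of the residual
    # onto one oscillation period (minimum at the touchdowns, maximum in
    # between); free of the selection bias a windowed extremum would have
    evidence = []
    for a, b in zip(grid, grid[1:]):
        seg = r[a : b + 1]
        n = seg.size
        if n < 4:
            evidence.append(0.0)
            continue
        template = -np.cos(2.0 * np.pi * np.arange(n) / (n - 1))
        template -= template.mean()
        norm = float(np.dot(template, template))
        evidence.append(float(np.dot(seg, template) / norm * 2.0))
    evidence = np.asarray(evidence)

    in_strong = (np.asarray(grid[:-1]) >= strong[0] - snap) & (
        np.asarray(grid[1:]) <= strong[-1] + snap
    )
    mu = float(np.median(evidence[in_strong])) if in_strong.any() else float(
        np.median(evidence)
    )
    if mu <= 0:
        return td_idx
    threshold = 0.5 * mu

    # maximum-sum contiguous run of (evidence - threshold): globally optimal
    # onset/offset of the oscillating region
    best, best_lo, best_hi = -np.inf, 0, 0
    run, run_lo = 0.0, 0
    for k, e in enumerate(evidence):
        gain = float(e) - threshold
        if run <= 0:
            run, run_lo = gain, k
        else:
            run += gain
        if run > best:
            best, best_lo, best_hi = run, run_lo, k
    if best <= 0:
        return td_idx
    return sorted(set(nodes[best_lo : best_hi + 2]))


def detect_step_events(
    t, v_detect, cfg: Optional[GaitConfig] = None
) -> list[StepEvent]:
    """Locate touchdown/toe-off events in the speed oscillation.

    ``v_detect`` is first detrended by subtracting a long moving average
    (window ``detrend_s``) so that the per-step oscillation is picked
    against a flat background even while the runner is still accelerating.
    Local minima of the residual become touchdowns, local maxima toe-offs.
    Extrema below ``min_prominence`` are rejected; same-kind neighbours are
    resolved by keeping the more extreme one; touchdown intervals outside
    the step-time bounds drop the weaker offending extremum.  With
    ``periodic_prune`` the touchdown chain is additionally validated
    against the estimated step period (recommended for noisy field data).
    The result alternates strictly.
    """
    cfg = cfg or GaitConfig()
    t = np.asarray(t, dtype=float)
    v = np.asarray(v_detect, dtype=float)
    if t.size != v.size:
        raise ConfigError("t and v_detect must have equal length")
    if t.size < 5:
        raise NoStepsDetected("trace too short")
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(cfg.min_step_time / dt)))

    wb = max(3, int(round(cfg.detrend_s / dt)))
    trend = moving_average(v, wb, 2)
    r = v - trend

    maxima, _ = find_peaks(r, prominence=cfg.min_prominence, distance=distance)
    minima, _ = find_peaks(-r, prominence=cfg.min_prominence, distance=distance)
    if minima.size < 2:
        raise NoStepsDetected(f"only {minima.size} touchdown(s) found")

    td_idx = [int(i) for i in minima]
    if cfg.periodic_prune:
        td_idx = _periodic_walk(r, td_idx, dt, cfg)
        if len(td_idx) < 2:
            raise NoStepsDetected("periodic validation left < 2 touchdowns")
        # one toe-off between each touchdown pair: strongest residual max
        events = []
        for a, b in zip(td_idx, td_idx[1:]):
            events.append(StepEvent(a, float(t[a]), "touchdown"))
            cand = maxima[(maxima > a) & (maxima < b)]
            if cand.size:
                to = int(cand[np.argmax(r[cand])])
            else:
                to = a + int(np.argmax(r[a : b + 1]))
            if a < to < b:
                events.append(StepEvent(to, float(t[to]), "toeoff"))
        events.append(
            StepEvent(td_idx[-1], float(t[td_idx[-1]]), "touchdown")
        )
    else:
        events = sorted(
            [StepEvent(int(i), float(t[i]), "toeoff") for i in maxima]
            + [StepEvent(int(i), float(t[i]), "touchdown") for i in td_idx],
            key=lambda ev: ev.index,
        )
        events = _alternate(events, r)

    # drop touchdowns that imply an impossibly short step, then re-alternate
    changed = True
    while changed:
        changed = False
        tds = [ev for ev in events if ev.kind == "touchdown"]
        for a, b in zip(tds, tds[1:]):
            interval = b.time - a.time
            if interval < cfg.min_step_time:
                weaker = a if r[a.index] > r[b.index] else b
                events = [ev for ev in events if ev is not weaker]
                events = _alternate(events, r)
                changed = True
                break
            if interval > cfg.max_step_time:
                logger.debug(
                    "step interval %.3f s at t=%.2f exceeds max_step_time",
                    interval,
                    a.time,
                )

    # an isolated leading/trailing touchdown separated from the chain by
    # more than max_step_time is an artifact of the quiet region around the
    # run boundaries: drop it when it is the weaker of the boundary pair
    changed = True
    while changed:
        changed = False
        tds = [ev for ev in events if ev.kind == "touchdown"]
        if len(tds) > 2:
            first_gap = tds[1].time - tds[0].time
            if first_gap > cfg.max_step_time and (
                r[tds[0].index] > r[tds[1].index]
            ):
                events = [ev for ev in events if ev is not tds[0]]
                changed = True
                continue
            last_gap = tds[-1].time - tds[-2].time
            if last_gap > cfg.max_step_time and (
                r[tds[-1].index] > r[tds[-2].index]
            ):
                events = [ev for ev in events if ev is not tds[-1]]
                changed = True
    events = _alternate(events, r)
    # strip leading/trailing toe-offs left hanging by the pruning
    while events and events[0].kind == "toeoff" and len(events) > 1:
        if any(ev.kind == "touchdown" for ev in events):
            break
        events.pop(0)

    touchdowns = [ev for ev in events if ev.kind == "touchdown"]
    if len(touchdowns) < 2:
        raise NoStepsDetected(
            f"only {len(touchdowns)} touchdown(s) found"
        )
    if cfg.refine_subsample:
        events = [
            replace(ev, time=_refine_time(t, r, ev.index, cfg.refine_halfwidth))
            for ev in events
        ]
    return events


def compute_step_metrics(
    events: list[StepEvent], t, x, v=None
) -> list[Step]:
    """Derive per-step timings, length and frequency from the event list.

    For each consecutive touchdown pair with exactly one toe-off between
    them: ``support = toeoff - touchdown``, ``flight = next_touchdown -
    toeoff``, ``step = support + flight``; the step length is the
    displacement between the two touchdowns (x interpolated at event
    times).  Pairs without a unique toe-off are skipped and logged, but
    keep consuming an ordinal so side alternation stays consistent.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    touchdowns = [ev for ev in events if ev.kind == "touchdown"]
    if len(touchdowns) < 2:
        raise NoStepsDetected("need at least two touchdowns")
    toeoffs = [ev for ev in events if ev.kind == "toeoff"]

    steps: list[Step] = []
    n_pairs = len(touchdowns) - 1
    for k in range(n_pairs):
        td, td_next = touchdowns[k], touchdowns[k + 1]
        between = [ev for ev in toeoffs if td.time < ev.time < td_next.time]
        if len(between) != 1:
            logger.warning(
                "step %d skipped: %d toe-offs between touchdowns "
                "at %.2f-%.2f s",
                k,
                len(between),
                td.time,
                td_next.time,
            )
            continue
        to = between[0]
        support = to.time - td.time
        flight = td_next.time - to.time
        step_time = support + flight  # identity exact by construction
        x0 = float(np.interp(td.time, t, x))
        x1 = float(np.interp(td_next.time, t, x))
        length = x1 - x0
        steps.append(
            Step(
                ordinal=k,
                side="unknown",
                t_touchdown=td.time,
                t_toeoff=to.time,
                t_next_touchdown=td_next.time,
                support_time=support,
                flight_time=flight,
                step_time=step_time,
                step_length=length,
                step_frequency=1.0 / step_time,
                mean_speed=length / step_time,
                boundary_step=(k == 0 or k == n_pairs - 1),
            )
        )
    if not steps:
        raise StepStructureError("no touchdown pair had a unique toe-off")
    return steps


def assign_sides(steps: list[Step], first_leg_on_start: str) -> list[Step]:
    """Alternate L/R starting from the leg that was forward at the start.

    Sides alternate by ordinal, so a skipped step (missing toe-off) does not
    flip the parity of the following steps.  ``unknown`` marks every side
    unknown and makes symmetry unavailable.
    """
    if first_leg_on_start not in ("L", "R", "unknown"):
        raise ConfigError("first_leg_on_start must be 'L', 'R' or 'unknown'")
    if first_leg_on_start == "unknown":
        return [replace(s, side="unknown") for s in steps]
    other = "R" if first_leg_on_start == "L" else "L"
    return [
        replace(s, side=first_leg_on_start if s.ordinal % 2 == 0 else other)
        for s in steps
    ]


def symmetry_index(steps: list[Step], variable: str) -> SymmetryReport:
    """Left/right symmetry of one step variable.

    ``SI% = 100 * |mean_L - mean_R| / (0.5 * (mean_L + mean_R))`` — the
    absolute difference relative to the left/right mean, in percent.
    """
    if variable not in _VARIABLE_ATTR:
        raise ConfigError(
            f"unknown variable {variable!r}; choose from {SYMMETRY_VARIABLES}"
        )
    attr = _VARIABLE_ATTR[variable]
    left = [getattr(s, attr) for s in steps if s.side == "L"]
    right = [getattr(s, attr) for s in steps if s.side == "R"]
    if not left or not right:
        raise SymmetryUnavailable(
            f"need steps on both sides (L={len(left)}, R={len(right)})"
        )
    mean_l = float(np.mean(left))
    mean_r = float(np.mean(right))
    denom = 0.5 * (mean_l + mean_r)
    if denom == 0:
        raise SymmetryUnavailable("left/right mean is zero")
    si = 100.0 * abs(mean_l - mean_r) / denom
    return SymmetryReport(
        variable=variable,
        mean_left=mean_l,
        mean_right=mean_r,
        symmetry_index=si,
    )


def steps_to_frame(steps: list[Step]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ordinal": [s.ordinal for s in steps],
            "side": [s.side for s in steps],
            "t_touchdown": [s.t_touchdown for s in steps],
            "t_toeoff": [s.t_toeoff for s in steps],
            "support_s": [s.support_time for s in steps],
            "flight_s": [s.flight_time for s in steps],
            "step_s": [s.step_time for s in steps],
            "length_m": [s.step_length for s in steps],
            "frequency_hz": [s.step_frequency for s in steps],
            "mean_speed": [s.mean_speed for s in steps],
            "boundary_step": [s.boundary_step for s in steps],
        }
    )
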