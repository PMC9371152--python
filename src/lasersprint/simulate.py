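"""Synthetic 100 Hz sprint traces with exact ground truth.

The base speed profile is a mono-exponential rise ``v_max * (1 - exp(-t/tau))``
with an optional linear terminal decay once the runner passes
``decay_onset``.  A zero-mean per-step modulation is superposed: each step
cycle consists of a support segment (speed rising linearly from -A to +A)
followed by a flight segment (falling from +A back to -A), so every
touchdown is a speed minimum and every toe-off a maximum, exactly matching
the event definitions the gait module detects.  Displacement is obtained in
closed form (the base integral is analytic, the modulation is piecewise
linear), so ground-truth step lengths and split times are exact.

Step cycles begin only once the base profile's slope has dropped below a
fraction of the modulation's downward flight slope; earlier than that the
superposed speed curve would rise monotonically and the cycle would leave
no detectable extremum, which would make event-recovery comparisons
meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .ldm_io import RawTrace

__all__ = [
    "SimConfig",
    "StepTruth",
    "GroundTruth",
    "base_velocity",
    "base_displacement",
    "synthesize_trace",
    "ground_truth_summary",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic sprint."""

    v_max: float = 11.5  # m/s
    tau: float = 1.3  # s, acceleration time constant
    race_distance: float = 100.0  # m
    decay_onset: Optional[float] = 80.0  # m; None disables terminal decay
    decay_rate: float = 0.015  # fraction of v_max lost per 10 m past onset
    step_freq: float = 4.5  # Hz
    duty_factor: float = 0.45  # support fraction of the step
    osc_amplitude: float = 0.4  # m/s
    asym_step_time: float = 0.0  # signed fraction, L vs R step time
    asym_amplitude: float = 0.0  # signed fraction, L vs R oscillation
    noise_sd: float = 0.020  # m
    dropout_rate: float = 0.0  # per-sample probability of a NaN run start
    spike_rate: float = 0.0  # per-sample probability of a distance spike
    L1: float = 7.3  # m, laser-to-start-line distance
    pre_start_s: float = 1.0  # s of still signal before the start
    post_run_s: float = 1.5  # s sampled beyond the race distance
    rate: float = 100.0  # Hz
    seed: int = 0
    osc_onset_margin: float = 0.5  # base slope / flight slope at step onset
    tail_margin: float = 0.25  # s without new cycles before the trace end

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.tau <= 0 or self.step_freq <= 0:
            raise ConfigError("v_max, tau and step_freq must be > 0")
        if not (0.0 < self.duty_factor < 1.0):
            raise ConfigError("duty_factor must be in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.osc_amplitude < 0:
            raise ConfigError("osc_amplitude must be >= 0")
        if self.rate <= 0:
            raise ConfigError("rate must be > 0")
        if self.race_distance <= 0:
            raise ConfigError("race_distance must be > 0")
        step_min = (1.0 - abs(self.asym_step_time) / 2.0) / self.step_freq
        if self.osc_amplitude > 0 and step_min < 3.0 / self.rate:
            raise ConfigError(
                "step period shorter than 3 samples at the configured rate"
            )


def _decay_params(cfg: SimConfig) -> tuple[float, float]:
    """(t_d, c): time the decay starts and its linear coefficient."""
    if (
        cfg.decay_onset is None
        or cfg.decay_rate <= 0
        or cfg.decay_onset >= cfg.race_distance + 1000.0
    ):
        return math.inf, 0.0
    t_hi = cfg.decay_onset / cfg.v_max + 20.0 * cfg.tau

    def f(t: float) -> float:
        return _x_undecayed(t, cfg) - cfg.decay_onset

    t_d = brentq(f, 1e-9, t_hi, xtol=1e-12)
    c = cfg.decay_rate * cfg.v_max / 10.0  # per second
    return float(t_d), float(c)


def _v_undecayed(t, cfg: SimConfig):
    return cfg.v_max * (1.0 - np.exp(-np.asarray(t, dtype=float) / cfg.tau))


def _x_undecayed(t, cfg: SimConfig):
    t = np.asarray(t, dtype=float)
    return cfg.v_max * (t - cfg.tau * (1.0 - np.exp(-t / cfg.tau)))


def base_velocity(time, cfg: SimConfig):
    """Base (step-modulation-free) speed profile at ``time`` (s from start)."""
    t = np.asarray(time, dtype=float)
    v = _v_undecayed(t, cfg)
    t_d, c = _decay_params(cfg)
    if np.isfinite(t_d):
        factor = np.clip(1.0 - c * (t - t_d), 0.0, 1.0)
        v = np.where(t > t_d, v * factor, v)
    return v if np.ndim(time) else float(v)


def base_displacement(time, cfg: SimConfig):
    """Closed-form integral of :func:`base_velocity` from 0 to ``time``."""
    t = np.asarray(time, dtype=float)
    x = _x_undecayed(t, cfg)
    t_d, c = _decay_params(cfg)
    if np.isfinite(t_d):
        tau, vmax = cfg.tau, cfg.v_max
        dtd = t - t_d
        # G(t) = integral_{t_d}^{t} (s - t_d) * v_undecayed(s) ds
        g = vmax * (
            dtd**2 / 2.0
            + tau * dtd * np.exp(-t / tau)
            + tau**2 * np.exp(-t / tau)
            - tau**2 * math.exp(-t_d / tau)
        )
        x = np.where(t > t_d, x - c * g, x)
    return x if np.ndim(time) else float(x)


@dataclass
class StepTruth:
    ordinal: int
    side: str
    t_touchdown: float
    t_toeoff: float
    t_next_touchdown: float
    support_time: float
    flight_time: float
    step_time: float
    step_length: float
    step_frequency: float
    mean_speed: float


@dataclass
class GroundTruth:
    """True event table and profile summary of one synthetic sprint."""

    start_time: float  # s, absolute trace time of the first run sample
    touchdown_times: list[float]  # absolute trace time
    toeoff_times: list[float]
    steps: list[StepTruth]
    v_max_attained: float
    time_at_distance: float  # s from start to race_distance
    config: SimConfig

    def __post_init__(self) -> None:
        tds = np.asarray(self.touchdown_times)
        tos = np.asarray(self.toeoff_times)
        if tds.size and np.any(np.diff(tds) <= 0):
            raise ConfigError("touchdown times not strictly increasing")
        if tos.size and np.any(np.diff(tos) <= 0):
            raise ConfigError("toe-off times not strictly increasing")


class _Modulation:
    """Piecewise-linear per-step speed modulation with exact integral."""

    def __init__(self, knot_t: np.ndarray, knot_w: np.ndarray) -> None:
        self.kt = knot_t
        self.kw = knot_w
        if knot_t.size:
            seg = np.diff(knot_t)
            self.cum = np.concatenate(
                ([0.0], np.cumsum(seg * (knot_w[1:] + knot_w[:-1]) / 2.0))
            )
        else:
            self.cum = np.zeros(0)

    def value(self, t):
        if self.kt.size == 0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return np.interp(t, self.kt, self.kw, left=0.0, right=self.kw[-1])

    def integral(self, t):
        """Cumulative integral of the modulation from 0 to t (vectorized)."""
        t = np.asarray(t, dtype=float)
        if self.kt.size == 0:
            return np.zeros_like(t)
        out = np.zeros_like(t)
        j = np.searchsorted(self.kt, t, side="right")
        inside = (j > 0) & (j < self.kt.size)
        if np.any(inside):
            ji = j[inside]
            t0 = self.kt[ji - 1]
            w0 = self.kw[ji - 1]
            slope = (self.kw[ji] - w0) / (self.kt[ji] - t0)
            dt = t[inside] - t0
            wt = w0 + slope * dt
            out[inside] = self.cum[ji - 1] + dt * (w0 + wt) / 2.0
        after = j >= self.kt.size
        if np.any(after):
            out[after] = self.cum[-1] + (t[after] - self.kt[-1]) * self.kw[-1]
        return out


def _build_modulation(
    cfg: SimConfig, t_total: float
) -> tuple[_Modulation, list[float], list[float], list[str]]:
    """Construct step cycles; returns (modulation, TDs, TOs, sides)."""
    if cfg.osc_amplitude == 0.0:
        return _Modulation(np.zeros(0), np.zeros(0)), [], [], []

    amp = {
        "L": cfg.osc_amplitude * (1.0 + cfg.asym_amplitude / 2.0),
        "R": cfg.osc_amplitude * (1.0 - cfg.asym_amplitude / 2.0),
    }
    period = {
        "L": (1.0 + cfg.asym_step_time / 2.0) / cfg.step_freq,
        "R": (1.0 - cfg.asym_step_time / 2.0) / cfg.step_freq,
    }
    for side in ("L", "R"):
        if amp[side] <= 0 or period[side] <= 0:
            raise ConfigError("asymmetry makes one side's step degenerate")

    # steepest base slope a flight descent must still dominate
    flight_slope = min(
        2.0 * amp[s] / ((1.0 - cfg.duty_factor) * period[s]) for s in "LR"
    )
    target = cfg.osc_onset_margin * flight_slope
    ratio = target * cfg.tau / cfg.v_max
    t_on = 0.0 if ratio >= 1.0 else -cfg.tau * math.log(ratio)

    knot_t = [t_on]
    knot_w = [0.0]
    tds: list[float] = []
    tos: list[float] = []
    sides: list[str] = []
    side = "L"
    td = t_on + 0.5 * (1.0 - cfg.duty_factor) * period[side]
    while td + period[side] <= t_total - cfg.tail_margin:
        to = td + cfg.duty_factor * period[side]
        knot_t += [td, to]
        knot_w += [-amp[side], amp[side]]
        tds.append(td)
        tos.append(to)
        sides.append(side)
        td = td + period[side]
        side = "R" if side == "L" else "L"
    # closing touchdown of the last full step, then a short ramp back to
    # zero so the closing touchdown is a genuine local minimum even when
    # the base profile is already decaying
    knot_t.append(td)
    knot_w.append(-amp[side])
    tds.append(td)
    ramp = 0.5 * cfg.duty_factor / cfg.step_freq
    knot_t.append(td + ramp)
    knot_w.append(0.0)

    return (
        _Modulation(np.asarray(knot_t), np.asarray(knot_w)),
        tds,
        tos,
        sides,
    )


def synthesize_trace(cfg: SimConfig) -> tuple[RawTrace, GroundTruth]:
    """Generate one synthetic raw trace and its exact ground truth.

    Deterministic for a fixed ``cfg.seed``: all randomness (sensor noise,
    dropouts, spikes) flows through a single seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.rate

    # total run duration: time to race_distance on the base profile + tail
    t_hi = cfg.race_distance / cfg.v_max + 20.0 * cfg.tau
    t_race_base = brentq(
        lambda t: base_displacement(t, cfg) - cfg.race_distance,
        1e-9,
        t_hi,
        xtol=1e-12,
    )
    t_total = t_race_base + cfg.post_run_s

    mod, tds, tos, sides = _build_modulation(cfg, t_total)

    n_run = int(math.floor(t_total * cfg.rate)) + 1
    t_run = np.arange(n_run) / cfg.rate
    x_run = base_displacement(t_run, cfg) + mod.integral(t_run)

    n_pre = int(round(cfg.pre_start_s * cfg.rate))
    t_full = np.arange(n_pre + n_run) / cfg.rate
    x_full = np.concatenate((np.zeros(n_pre), x_run))
    d = cfg.L1 + x_full

    if cfg.noise_sd > 0:
        d = d + rng.normal(0.0, cfg.noise_sd, d.size)
    if cfg.dropout_rate > 0:
        starts = np.flatnonzero(rng.random(d.size) < cfg.dropout_rate)
        for i in starts:
            run_len = int(rng.integers(1, 6))
            d[i : i + run_len] = np.nan
        # keep at least the two boundary samples usable for repair anchoring
    if cfg.spike_rate > 0:
        hits = rng.random(d.size) < cfg.spike_rate
        d[hits] = d[hits] + rng.uniform(1.0, 3.0, int(hits.sum()))

    trace = RawTrace(t=t_full, d=d, nominal_rate=cfg.rate)

    # exact per-step truth
    def x_exact(t):
        return float(base_displacement(t, cfg) + mod.integral(np.asarray([t]))[0])

    steps: list[StepTruth] = []
    for k, (td, to, side) in enumerate(zip(tds, tos, sides)):
        td_next = tds[k + 1]
        length = x_exact(td_next) - x_exact(td)
        step_time = td_next - td
        steps.append(
            StepTruth(
                ordinal=k,
                side=side,
                t_touchdown=cfg.pre_start_s + td,
                t_toeoff=cfg.pre_start_s + to,
                t_next_touchdown=cfg.pre_start_s + td_next,
                support_time=to - td,
                flight_time=td_next - to,
                step_time=step_time,
                step_length=length,
                step_frequency=1.0 / step_time,
                mean_speed=length / step_time,
            )
        )

    v_run = base_velocity(t_run, cfg) + mod.value(t_run)
    v_max_attained = float(np.max(v_run))
    if tos:
        v_at_tos = base_velocity(np.asarray(tos), cfg) + mod.value(
            np.asarray(tos)
        )
        v_max_attained = max(v_max_attained, float(np.max(v_at_tos)))

    time_at_distance = float(
        brentq(
            lambda t: base_displacement(t, cfg)
            + mod.integral(np.asarray([t]))[0]
            - cfg.race_distance,
            1e-9,
            t_total,
            xtol=1e-12,
        )
    )

    truth = GroundTruth(
        start_time=n_pre / cfg.rate,
        touchdown_times=[cfg.pre_start_s + t for t in tds],
        toeoff_times=[cfg.pre_start_s + t for t in tos],
        steps=steps,
        v_max_attained=v_max_attained,
        time_at_distance=time_at_distance,
        config=cfg,
    )
    return trace, truth


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Per-step truth table in the same schema as the gait steps export."""
    steps = gt.steps
    n = len(steps)
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
            "boundary_step": [i in (0, n - 1) for i in range(n)],
        }
    )
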