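"""Reading, validating and calibrating laser distance-measurement traces.

A trace is a pair of equal-length arrays: sample time in seconds and raw
distance from the laser head to the target in meters, nominally sampled at
100 Hz.  Device exports are plain text, either two long rows (first row
time, second row distance) or two columns; both dialects are accepted, as
are ``.`` and ``,`` decimal separators and whitespace or ``;`` delimiters.

Calibration subtracts the laser-to-start-line distance ``L1`` so that the
``x`` axis becomes displacement past the start line.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, ConfigError, ParseError

# Beam-spot footprint of the rangefinder on the reflecting surface, quoted by
# the manufacturer at the near (10 m) and far (100 m) end of the working
# range, in mm^2.  Used only for documentation/reporting of device geometry.
BEAM_SPOT_AREA_NEAR_MM2 = 1548.0
BEAM_SPOT_AREA_FAR_MM2 = 19_900.0
BEAM_SPOT_NEAR_RANGE_M = 10.0
BEAM_SPOT_FAR_RANGE_M = 100.0

#: Device precision class (one-sided), meters.
DEVICE_PRECISION_M = 0.020


def beam_spot_area_ratio(ndigits: int = 1) -> float:
    """Ratio of the far-end to near-end beam spot area, rounded.

    Quantifies how much the laser footprint grows over the quoted
    10-100 m working range.
    """
    return round(BEAM_SPOT_AREA_FAR_MM2 / BEAM_SPOT_AREA_NEAR_MM2, ndigits)


@dataclass
class RawTrace:
    """As-parsed time/distance arrays from the device file.

    Parameters
    ----------
    t : ndarray
        Sample times, seconds, strictly increasing.
    d : ndarray
        Distance from the laser to the target, meters.  NaN marks missing
        samples (beam dropouts).
    nominal_rate : float
        Nominal sampling rate in Hz (default 100).
    """

    t: np.ndarray
    d: np.ndarray
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.d.ndim != 1:
            raise ParseError("time and distance must be 1-D arrays")
        if self.t.size != self.d.size:
            raise ParseError(
                f"time ({self.t.size}) and distance ({self.d.size}) "
                "sample counts differ"
            )
        if self.t.size == 0:
            raise ParseError("empty trace")
        if not np.all(np.isfinite(self.t)):
            raise ParseError("non-finite sample times")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ParseError("sample times are not strictly increasing")
            med = float(np.median(dt))
            expected = 1.0 / self.nominal_rate
            if not (0.9 * expected <= med <= 1.1 * expected):
                raise ParseError(
                    f"median sampling interval {med:.6g} s deviates more "
                    f"than 10% from nominal {expected:.6g} s"
                )

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def median_dt(self) -> float:
        if self.t.size < 2:
            return 1.0 / self.nominal_rate
        return float(np.median(np.diff(self.t)))


@dataclass
class Athlete:
    name: str = ""
    birth_date: str = ""
    country: str = ""
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    left_leg_length_cm: Optional[float] = None
    right_leg_length_cm: Optional[float] = None


@dataclass
class MeasurementMeta:
    """Measurement description record accompanying one trace."""

    place: str = ""
    date: str = ""
    wind: Optional[float] = None  # m/s, signed
    official_time: Optional[float] = None  # s
    reaction_time: Optional[float] = None  # s
    measured_distance: float = 100.0  # m
    athlete: Athlete = field(default_factory=Athlete)
    sport_discipline: str = ""
    dominant_hand: str = "unknown"  # L | R | unknown
    dominant_leg: str = "unknown"
    first_leg_on_start: str = "unknown"  # L | R | unknown
    start_type: str = "static-low"  # moving | static-high | static-low
    calibration_distance_L1: float = 7.3  # m
    max_speed_tolerance: float = 0.02  # fraction of v_max
    notes: str = ""

    def __post_init__(self) -> None:
        if self.calibration_distance_L1 <= 0:
            raise CalibrationError("calibration_distance_L1 must be > 0")
        if not (0.0 < self.max_speed_tolerance < 0.5):
            raise ConfigError(
                f"max_speed_tolerance {self.max_speed_tolerance} "
                "outside (0, 0.5)"
            )
        for name in ("dominant_hand", "dominant_leg", "first_leg_on_start"):
            if getattr(self, name) not in ("L", "R", "unknown"):
                raise ValueError(f"{name} must be 'L', 'R' or 'unknown'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MeasurementMeta":
        data = dict(data)
        athlete = data.pop("athlete", None) or {}
        if isinstance(athlete, dict):
            athlete = Athlete(**athlete)
        return cls(athlete=athlete, **data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MeasurementMeta":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass
class CalibratedTrace:
    """Displacement past the start line: ``x = d - L1``."""

    t: np.ndarray
    x: np.ndarray
    L1: float
    nominal_rate: float = 100.0
    meta: Optional[MeasurementMeta] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def median_dt(self) -> float:
        if self.t.size < 2:
            return 1.0 / self.nominal_rate
        return float(np.median(np.diff(self.t)))

    def replace(self, **kw) -> "CalibratedTrace":
        return dataclasses.replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _tokenize_line(line: str) -> list[str]:
    return [tok for tok in line.replace(";", " ").split() if tok]


def _to_float(token: str) -> float:
    try:
        return float(token.replace(",", "."))
    except ValueError as exc:
        raise ParseError(f"cannot decode numeric token {token!r}") from exc


def parse_ldm_text(
    text: str,
    dialect: str = "auto",
    millimeters: bool = False,
    nominal_rate: Optional[float] = None,
) -> RawTrace:
    """Parse a device text export into a :class:`RawTrace`.

    Parameters
    ----------
    text : str
        Raw file content.  Two dialects are supported: ``row-wise`` (first
        row all times, second row all distances) and ``column-wise`` (one
        time/distance pair per line).  ``auto`` resolves by shape.
    millimeters : bool
        If True, distances are divided by 1000.
    nominal_rate : float, optional
        Override the sampling rate inferred from the median time step.
    """
    if dialect not in ("auto", "row-wise", "column-wise"):
        raise ParseError(f"unknown dialect {dialect!r}")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty file")
    rows = [_tokenize_line(ln) for ln in lines]

    if dialect == "auto":
        # exactly two lines -> device-native row-wise (covers the ambiguous
        # 2x2 case); otherwise two columns per line
        if len(rows) == 2:
            dialect = "row-wise"
        elif all(len(r) == 2 for r in rows):
            dialect = "column-wise"
        else:
            raise ParseError(
                "cannot infer dialect: expected 2 rows or 2 columns"
            )

    if dialect == "row-wise":
        if len(rows) != 2:
            raise ParseError(
                f"row-wise dialect needs exactly 2 rows, got {len(rows)}"
            )
        t_tokens, d_tokens = rows
    else:
        bad = [i for i, r in enumerate(rows) if len(r) != 2]
        if bad:
            raise ParseError(
                f"column-wise dialect needs 2 columns; line {bad[0] + 1} "
                f"has {len(rows[bad[0]])}"
            )
        t_tokens = [r[0] for r in rows]
        d_tokens = [r[1] for r in rows]

    if len(t_tokens) != len(d_tokens):
        raise ParseError(
            f"time ({len(t_tokens)}) and distance ({len(d_tokens)}) "
            "counts differ"
        )

    t = np.array([_to_float(tok) for tok in t_tokens])
    d = np.array(
        [np.nan if tok.lower() == "nan" else _to_float(tok) for tok in d_tokens]
    )
    if millimeters:
        d = d / 1000.0

    if nominal_rate is None:
        if t.size > 1:
            med = float(np.median(np.diff(t)))
            if med <= 0:
                raise ParseError("sample times are not strictly increasing")
            nominal_rate = 1.0 / med
            # snap to an integer rate when within rounding distance
            if (
                round(nominal_rate) >= 1
                and abs(nominal_rate - round(nominal_rate)) < 0.05
            ):
                nominal_rate = float(round(nominal_rate))
        else:
            nominal_rate = 100.0

    return RawTrace(t=t, d=d, nominal_rate=nominal_rate)


def serialize_trace(trace: RawTrace, dialect: str = "row-wise") -> str:
    """Write a trace back to device-dialect text.

    Uses ``repr`` formatting so that parse -> serialize -> parse round-trips
    every float bit-exactly.
    """
    t_tok = [repr(float(v)) for v in trace.t]
    d_tok = ["nan" if np.isnan(v) else repr(float(v)) for v in trace.d]
    buf = io.StringIO()
    if dialect == "row-wise":
        buf.write(" ".join(t_tok) + "\n")
        buf.write(" ".join(d_tok) + "\n")
    elif dialect == "column-wise":
        for a, b in zip(t_tok, d_tok):
            buf.write(f"{a} {b}\n")
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    return buf.getvalue()


def apply_calibration(
    trace: RawTrace,
    L1: float,
    meta: Optional[MeasurementMeta] = None,
) -> CalibratedTrace:
    """Shift raw distances by the start-line calibration distance.

    ``x_i = d_i - L1`` for every sample; time is unchanged.
    """
    if L1 <= 0:
        raise CalibrationError(f"L1 must be > 0, got {L1}")
    return CalibratedTrace(
        t=trace.t.copy(),
        x=trace.d - L1,
        L1=float(L1),
        nominal_rate=trace.nominal_rate,
        meta=meta,
    )
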