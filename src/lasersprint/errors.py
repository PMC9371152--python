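"""Exception hierarchy for the lasersprint pipeline.

Every stage raises a dedicated subclass of :class:`LaserSprintError` so the
CLI can map any pipeline failure to a non-zero exit code while tests can
assert on the precise failure mode.
"""


class LaserSprintError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(LaserSprintError):
    """Raw trace text could not be decoded into a valid time/distance pair."""


class CalibrationError(LaserSprintError):
    """Invalid calibration distance."""


class ConfigError(LaserSprintError):
    """A configuration value violates its contract."""


class RepairError(LaserSprintError):
    """Artifact repair is impossible (e.g. nothing clean left to anchor on)."""


class NoStartDetected(LaserSprintError):
    """The displacement never rises and holds above the start threshold."""


class EndNotReached(LaserSprintError):
    """The displacement never exceeds the configured end distance."""


class ComputeError(LaserSprintError):
    """A kinematic computation received input it cannot handle."""


class NoStepsDetected(LaserSprintError):
    """Fewer than two touchdown events found in the velocity oscillation."""


class StepStructureError(LaserSprintError):
    """A touchdown pair without exactly one toe-off between them."""


class SymmetryUnavailable(LaserSprintError):
    """Left/right comparison impossible (side unknown or one side empty)."""


class StatsError(LaserSprintError):
    """Invalid input to a statistics routine."""


class CorrelationUndefined(LaserSprintError):
    """Pearson correlation undefined (zero variance)."""


class ReportError(LaserSprintError):
    """A mandatory pipeline stage is missing from the report inputs."""
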