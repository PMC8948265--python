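"""Exception hierarchy for the uwheel package."""


class UWheelError(Exception):
    """Base class for all uwheel errors."""


class ParameterError(UWheelError, ValueError):
    """A physical parameter is outside its valid domain."""


class InvalidRadiusError(ParameterError):
    """Wheel radius smaller than a single bead radius."""


class AngleDomainError(ParameterError):
    """Incline or switchback angle outside its valid range."""


class PinnedWheelError(UWheelError):
    """Normal load exceeds the maximum electrostatic repulsion.

    The lubrication gap has no positive solution: the wheel is pinned
    against the wall.  Raised distinctly from parameter errors so callers
    can treat a pinned wheel as a physical regime, not a bad input.
    """


class ConfigError(UWheelError, ValueError):
    """Malformed or schema-violating configuration input."""


class NetworkValidationError(UWheelError, ValueError):
    """A network violates structural invariants.

    ``issues`` holds one human-readable string per violation.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


class PathError(UWheelError, ValueError):
    """Query position outside the planned path, or unreachable target."""


class EmptySwarmError(UWheelError, ValueError):
    """An operation requiring alive wheels was called on an empty swarm."""


class CalibrationError(UWheelError, ValueError):
    """Fluorescence calibration impossible (e.g. zero post-threshold signal)."""


class ScanFormatError(UWheelError, ValueError):
    """Scan raster is not a 16-bit single-plane grayscale image."""
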