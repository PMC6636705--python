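"""Exception hierarchy.

All package-raised errors derive from :class:`LaminaProbeError`, so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class LaminaProbeError(Exception):
    """Base class for all errors raised by laminaprobe."""


class ConfigError(LaminaProbeError):
    """Invalid configuration value or combination."""


class SchemaError(LaminaProbeError):
    """A table or file does not match the documented schema."""


class CalibrationError(LaminaProbeError):
    """A calibration target cannot be met (e.g. root-finding failed)."""


class OnsetError(LaminaProbeError):
    """Automatic H-reflex onset detection failed; manual onset required."""


class SearchError(LaminaProbeError):
    """The earliest-facilitation search cannot proceed."""


class FitError(LaminaProbeError):
    """A model fit (e.g. membrane time constant) failed."""


class DependencyError(LaminaProbeError):
    """A pipeline stage is missing an input produced by an earlier stage."""
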