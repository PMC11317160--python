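"""Exception hierarchy.

Every error raised by this package derives from :class:`ForkrestartError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class ForkrestartError(Exception):
    """Base class for all errors raised by forkrestart."""

    #: short machine-greppable tag, overridden by subclasses
    tag = "error"


class TrackFormatError(ForkrestartError):
    """Malformed bedGraph/wiggle input (unsorted, overlapping, wrong width)."""

    tag = "track-format"


class UnsupportedInputError(ForkrestartError):
    """Input is well-formed but outside the supported dialect (e.g. multi-reference)."""

    tag = "unsupported-input"


class AlignmentError(ForkrestartError):
    """Tracks that must share a binning do not."""

    tag = "alignment"


class ConfigError(ForkrestartError):
    """Missing or malformed configuration (manifest roles, config file keys)."""

    tag = "config"


class NormalizationError(ForkrestartError):
    """A library track cannot be normalized (e.g. all zeros)."""

    tag = "normalization"


class ParameterError(ForkrestartError):
    """A parameter value is outside its valid domain."""

    tag = "parameter"


class WindowError(ForkrestartError):
    """An analysis window is invalid or contains too few usable bins."""

    tag = "window"


class ProgressionUndefinedError(ForkrestartError):
    """Progression cannot be estimated (no restart signal)."""

    tag = "progression-undefined"


class ComparisonError(ForkrestartError):
    """Strain comparison undefined (reference restart fraction is zero)."""

    tag = "comparison"


class SimulationError(ForkrestartError):
    """The replication simulation left part of the locus unreplicated."""

    tag = "simulation"
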