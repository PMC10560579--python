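"""Exception types shared across the package."""


class NetburstsError(Exception):
    """Base class for package-specific errors."""


class ConfigError(NetburstsError, ValueError):
    """A configuration value is missing or invalid; names the offending field."""


class FormatError(NetburstsError, ValueError):
    """A signal container or sidecar is malformed or lacks required metadata."""


class IntegrityError(NetburstsError, ValueError):
    """Container metadata disagrees with the payload (e.g. channel counts)."""


class BaselineUnavailableError(NetburstsError, RuntimeError):
    """No non-burst gap long enough to estimate a baseline spectrum.

    Callers may fall back to a whole-recording baseline or an explicit
    baseline segment supplied in the configuration.
    """


class DegenerateStatisticError(NetburstsError, ValueError):
    """A test statistic is undefined for the given data (e.g. zero variance)."""


class UnresolvedLabelError(NetburstsError, RuntimeError):
    """Cluster-to-class mapping could not be decided; manual override needed."""
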