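"""Exception hierarchy for schoolnet."""


class SchoolnetError(Exception):
    """Base class for all schoolnet errors."""


class ConfigError(SchoolnetError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ConsistencyError(SchoolnetError, ValueError):
    """Inputs reference each other inconsistently (e.g. unknown node id)."""


class UndefinedError(SchoolnetError, ValueError):
    """A statistic is undefined for the given input (e.g. density of n<2)."""


class FitError(SchoolnetError, ValueError):
    """Distribution fit cannot be performed on the given sample."""


class FormatError(SchoolnetError, ValueError):
    """A file does not parse under the declared format."""
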