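"""Exception hierarchy shared across the pipeline."""


class NPPTrendsError(Exception):
    """Base class for all package errors."""


class InvalidGridError(NPPTrendsError):
    """Grid edges are non-monotone, out of range, or inconsistent."""


class EmptyDomainError(NPPTrendsError):
    """A reduction was requested over zero valid (unmasked, non-missing) cells."""


class FormatError(NPPTrendsError):
    """A file is missing required coordinates or metadata (e.g. units)."""


class InsufficientDataError(NPPTrendsError):
    """Too few valid observations for the requested statistic."""


class ConfigError(NPPTrendsError):
    """A configuration value is out of its valid range."""


class UnitsError(NPPTrendsError):
    """Fields carry incompatible or missing units."""
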