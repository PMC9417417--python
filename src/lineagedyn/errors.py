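"""Exception hierarchy shared across the package."""


class LineagedynError(Exception):
    """Base class for all package errors."""


class SchemaError(LineagedynError):
    """A required column cannot be resolved in an input table."""


class DataError(LineagedynError):
    """Input rows are malformed (duplicates, bad values, empty traces)."""


class TopologyError(LineagedynError):
    """Parent/child structure of a forest is inconsistent."""


class NotApplicableError(LineagedynError):
    """An operation was requested on a cell whose fate does not support it."""


class InsufficientDataError(LineagedynError):
    """Too few observations for the requested statistic."""


class ConfigError(LineagedynError):
    """Mismatched or invalid configuration for an operation."""


class DegenerateClusterError(LineagedynError):
    """Clustering cannot proceed (e.g. all values identical)."""


class AlignmentError(LineagedynError):
    """Cluster alignment cannot be computed (e.g. too few shared genes)."""
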