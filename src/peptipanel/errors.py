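"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PeptipanelError` so callers (and the
CLI) can catch pipeline failures without swallowing programming errors.
"""


class PeptipanelError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PeptipanelError):
    """A file does not have the expected columns/structure."""


class ParseError(PeptipanelError):
    """A cell could not be parsed; the message names the offending line."""


class MissingDataError(PeptipanelError):
    """Samples listed in metadata without corresponding data files."""


class ValidationError(PeptipanelError):
    """Inputs violate a documented precondition."""


class ConfigError(PeptipanelError):
    """An impossible or inconsistent configuration."""


class SelectionError(PeptipanelError):
    """Housekeeping selection cannot satisfy its constraints."""


class NormalizationError(PeptipanelError):
    """A sample detects too few housekeeping peptides to be normalized."""


class PowerError(ValidationError):
    """A comparison group is too small for a meaningful rank test."""
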