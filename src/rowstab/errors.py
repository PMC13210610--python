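"""Exception hierarchy for the rowstab pipeline."""


class RowstabError(Exception):
    """Base class for all rowstab errors."""


class FormatError(RowstabError):
    """A delimited-text input does not have the expected layout (e.g. a
    mapped column is missing)."""


class DataError(RowstabError):
    """The input parses but its content violates a precondition (non-
    increasing time, too few rows, missing manifest cells, ...)."""


class ConfigError(RowstabError):
    """A configuration value is out of its admissible range."""


class SegmentationError(RowstabError):
    """Stroke segmentation cannot produce at least one complete stroke."""
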