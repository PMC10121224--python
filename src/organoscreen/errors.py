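"""Exception hierarchy shared across the pipeline stages."""


class ScreenError(Exception):
    """Base class for all organoscreen errors."""


class PlateParseError(ScreenError):
    """A plate-table or layout row could not be parsed.

    Carries the offending file, 1-based line number, and field name so a
    screening operator can fix the export by hand.
    """

    def __init__(self, path, line, field, message):
        self.path = str(path)
        self.line = line
        self.field = field
        super().__init__(f"{self.path}:{line}: field '{field}': {message}")


class DuplicateWellError(ScreenError):
    """The same (plate_id, row, col) appeared more than once."""


class QCError(ScreenError):
    """A plate cannot support the requested quality-control statistics."""


class NormalizationError(ScreenError):
    """Control wells are missing or degenerate for intra-plate normalization."""


class ConfigError(ScreenError):
    """A configuration value is outside its documented range."""
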