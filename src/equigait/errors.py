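"""Exception hierarchy for the equigait pipeline."""


class EquigaitError(Exception):
    """Base class for all equigait errors."""


class FormatError(EquigaitError):
    """A trajectory file does not follow the expected CSV dialect."""


class ParseError(EquigaitError):
    """A cell in a trajectory file could not be parsed as a number."""


class ValidationError(EquigaitError):
    """A value violates a domain invariant (e.g. likelihood outside [0, 1])."""


class ConfigurationError(EquigaitError):
    """A required bodypart or metadata field is missing or inconsistent."""


class InsufficientDataError(EquigaitError):
    """Too few usable frames survive filtering to compute a statistic."""


class InsufficientStridesError(InsufficientDataError):
    """Fewer than two stance onsets were found in a limb trajectory."""
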