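"""Exception hierarchy shared by all fuzzmap modules."""


class FuzzmapError(Exception):
    """Base class for all errors raised by fuzzmap."""


class InvalidInputError(FuzzmapError, ValueError):
    """A value violates a documented precondition (names the offending field)."""


class ParseError(FuzzmapError, ValueError):
    """A file record could not be interpreted (carries marker/record context)."""


class GridMismatchError(FuzzmapError, ValueError):
    """Two window tracks do not share the same chromosome or window grid."""


class InsufficientIndividualsError(FuzzmapError, ValueError):
    """A bulk was requested that exceeds the number of eligible individuals."""


class SelectionError(FuzzmapError, RuntimeError):
    """Marker-assisted selection could not find a suitable progeny in bound."""


class ConfigError(FuzzmapError, ValueError):
    """A run configuration value violates a module constraint."""
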