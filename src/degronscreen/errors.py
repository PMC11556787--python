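"""Exception hierarchy shared across the pipeline stages."""


class DegronScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DegronScreenError, ValueError):
    """A config object or file is internally inconsistent."""


class AlphabetError(DegronScreenError, ValueError):
    """A sequence contains characters outside the expected alphabet."""


class LengthError(DegronScreenError, ValueError):
    """A sequence has an invalid length (e.g. not a multiple of 3)."""


class InsufficientDataError(DegronScreenError, ValueError):
    """Not enough observations to perform the requested computation."""


class ParseError(DegronScreenError, ValueError):
    """A file could not be parsed; message carries location context."""
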