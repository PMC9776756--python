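"""Exception hierarchy for rdeep."""


class RdeepError(Exception):
    """Base class for all rdeep errors."""


class ConfigError(RdeepError):
    """Invalid configuration (bad scenario mixture, missing keys, ...)."""


class ParseError(RdeepError):
    """A table could not be parsed or failed validation; names the row."""


class InvalidParameterError(RdeepError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive width)."""
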