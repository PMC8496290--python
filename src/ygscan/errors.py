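"""Exception types shared across the pipeline.

``InputError`` maps to CLI exit code 2 (bad or unreadable data),
``ConfigError`` to exit code 3 (parameter values outside their invariants).
"""


class YgsError(Exception):
    """Base class for all ygscan errors."""


class InputError(YgsError):
    """Raised for unreadable, malformed, or empty input data."""


class ConfigError(YgsError):
    """Raised for parameter values that violate their invariants."""
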