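"""Exception hierarchy. All user-facing errors derive from ProtgradError."""


class ProtgradError(ValueError):
    """Base class for user-correctable errors (bad config, bad data, bad call)."""


class ConfigError(ProtgradError):
    """Invalid configuration value or combination."""


class ParseError(ProtgradError):
    """Malformed input table; message names the offending row/column."""


class DegenerateDataError(ProtgradError):
    """Data too degenerate for the requested statistic (constant variable, empty set...)."""
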