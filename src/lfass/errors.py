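"""Exception types shared across the package."""


class LfassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LfassError):
    """An input file violates the expected schema (bad header, duplicate
    wells, non-monotone times, ...). CLI maps this to exit code 2."""


class ConfigError(LfassError):
    """A configuration block is invalid (unknown keys, out-of-range
    parameters). CLI maps this to exit code 1."""
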