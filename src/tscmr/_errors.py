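"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2, ``ConfigError`` to exit code 3.
"""


class TscmrError(Exception):
    """Base class for all package-specific errors."""


class InputError(TscmrError):
    """Malformed or unusable data (bad values, empty tables, too few SNPs)."""


class ConfigError(TscmrError):
    """Invalid configuration (missing columns, bad thresholds, bad options)."""
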