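"""Exception hierarchy.

Command-line entry points map these onto exit codes: configuration and
usage problems exit 2, data/format problems exit 3, numerical failures
exit 4.
"""


class CardynError(Exception):
    """Base class for all package errors."""


class ConfigError(CardynError):
    """Invalid configuration: bad domain map, unknown keys, bad arguments."""


class FormatError(CardynError):
    """Unparsable or internally inconsistent input file."""


class SelectionError(CardynError):
    """A selection resolved to nothing or referenced an unknown name."""


class NumericalError(CardynError):
    """Degenerate geometry, instability, or otherwise failed numerics."""
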