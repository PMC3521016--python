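"""Exception hierarchy with CLI exit codes.

Exit-code convention: 0 ok, 2 configuration problem, 3 unreadable or
malformed input, 4 numerical failure.
"""


class HetdissectError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(HetdissectError):
    """Invalid configuration: bad column map, missing path, bad parameter."""

    exit_code = 2


class DomainError(HetdissectError, ValueError):
    """Argument outside the mathematical domain of an operation."""

    exit_code = 2


class InputError(HetdissectError):
    """Input data present but unusable (empty file, zero overlap, ...)."""

    exit_code = 3


class PanelLookupError(HetdissectError, KeyError):
    """Marker not present in the haplotype panel."""

    exit_code = 3


class NumericalError(HetdissectError):
    """Numerical failure such as a collinear design matrix."""

    exit_code = 4
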