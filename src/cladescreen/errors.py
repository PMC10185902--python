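"""Exception hierarchy shared by all stages.

Each class maps to a distinct CLI exit code (see ``cladescreen.cli``).
"""


class CladescreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(CladescreenError):
    """Malformed input text (Newick, VCF, TSV, BED)."""

    exit_code = 3


class ValidationError(CladescreenError):
    """Structurally parseable input that violates a documented contract."""

    exit_code = 4


class ConfigError(CladescreenError):
    """Invalid or infeasible run configuration."""

    exit_code = 5


class ContractError(CladescreenError):
    """A function precondition was violated by the caller."""

    exit_code = 6
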