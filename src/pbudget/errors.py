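"""Exception hierarchy for the budget pipeline.

Exit-code mapping used by the CLI: ``DataError`` -> 1, ``ConfigurationError`` -> 2.
"""


class PBudgetError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PBudgetError):
    """Invalid site configuration; message names the offending field."""


class DataError(PBudgetError):
    """Input tables are missing, malformed or internally inconsistent."""


class DomainError(PBudgetError, ValueError):
    """An operation was called outside its mathematical domain."""
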