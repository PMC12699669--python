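"""Exception hierarchy.

``InputError`` marks malformed user-supplied data (bad files, invalid labels,
inconsistent tables) and maps to exit status 2 in the CLI; anything else that
escapes is an internal error (exit status 1).
"""


class HomoeokitError(Exception):
    """Base class for all package errors."""


class InputError(HomoeokitError):
    """Malformed or inconsistent user input (file contents, labels, configs)."""


class ContractError(HomoeokitError):
    """An API precondition was violated by the caller."""
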