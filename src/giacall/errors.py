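"""Exception hierarchy for the ancestry-inference workflow.

Each pipeline stage raises a subclass of :class:`GiaError` so that callers
(notably the CLI) can map failure modes to distinct exit codes.
"""


class GiaError(Exception):
    """Base class for all workflow errors."""


class ValidationError(GiaError):
    """Malformed or inconsistent user input (labels, config, truth tables)."""


class ContractError(GiaError):
    """A documented precondition of an operation was violated by the caller."""


class EmptyInputError(GiaError):
    """An input file yielded no usable records."""


class EmptyOutputError(GiaError):
    """A filtering stage removed every record; carries the stage name."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no records survived stage '{stage}'")
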