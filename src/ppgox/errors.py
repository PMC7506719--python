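"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config errors -> 2, data/format
errors -> 3, degenerate-signal errors -> 4).
"""


class PPGOxError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PPGOxError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(PPGOxError, ValueError):
    """A file or in-memory record violates the documented format/invariants."""


class DegenerateSignalError(PPGOxError, ValueError):
    """A signal is unusable for the requested stage (e.g. too few extrema).

    Carries enough context to name the offending channel and stage.
    """

    def __init__(self, message: str, channel: str | None = None, stage: str | None = None):
        prefix = ""
        if channel is not None:
            prefix += f"channel '{channel}'"
        if stage is not None:
            prefix += (" " if prefix else "") + f"at stage '{stage}'"
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.channel = channel
        self.stage = stage


class UndefinedResultError(PPGOxError, ValueError):
    """The requested quantity is undefined for the given input (e.g. no events)."""
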