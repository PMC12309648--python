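"""Exception types shared across the pipeline stages."""


class MpametaError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MpametaError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(MpametaError, KeyError):
    """A required record (species, regulation row, file) is absent."""


class InsufficientReplicationError(MpametaError, ValueError):
    """Too few replicates to compute a variance (n < 2 on a side)."""


class UndefinedRatioError(MpametaError, ValueError):
    """A log response ratio is undefined (nonpositive mean after adjustment)."""


class IllPosedError(MpametaError, ValueError):
    """A model has more basis dimensions than observations."""
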