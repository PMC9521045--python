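"""Exception hierarchy shared across the pipeline."""


class LacteconError(Exception):
    """Base class for all package errors."""


class DomainError(LacteconError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InvalidConfigError(LacteconError, ValueError):
    """A configuration object violates its invariants."""


class InsufficientDataError(LacteconError, ValueError):
    """Too few observations to perform the requested computation."""


class DegenerateDataError(LacteconError, ValueError):
    """Data are formally sufficient but carry no usable signal."""


class IntegrityError(LacteconError, ValueError):
    """An input table violates a key/uniqueness contract."""
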