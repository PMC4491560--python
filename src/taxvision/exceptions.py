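"""Exception hierarchy shared across the package."""


class TaxvisionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TaxvisionError, ValueError):
    """A configuration object violates its invariants."""


class InputError(TaxvisionError, ValueError):
    """An input array or label set violates an operation's precondition."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate for the requested computation
    (constant image, foreground collapsed onto one row/column, zero radius)."""


class RankError(InputError):
    """More basis vectors requested than the centered data can support."""


class DataError(TaxvisionError):
    """A dataset on disk is missing, empty, or inconsistent."""
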