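"""Exception hierarchy.

``DomainError`` and ``UsageError`` signal bad inputs (physics-invalid
parameters vs. misuse of an API contract); ``EstimationError`` and
``ComputationError`` signal failures of a numerical procedure on inputs
that were individually valid; ``IntegrityError`` signals corruption of a
packaged data file.
"""


class LeednaError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LeednaError, ValueError):
    """A physical parameter is outside its admissible domain."""


class UsageError(LeednaError, ValueError):
    """An operation was called with inputs that violate its contract."""


class EstimationError(LeednaError, RuntimeError):
    """A statistical estimate could not be identified from the data."""


class ComputationError(LeednaError, RuntimeError):
    """A numerical routine failed to converge to the requested tolerance."""


class IntegrityError(LeednaError, RuntimeError):
    """A packaged data file does not match its recorded checksum."""
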