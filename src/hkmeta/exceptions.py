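"""Exception hierarchy for hkmeta.

All validation failures raise a subclass of :class:`HkmetaError`, so callers
(and the command-line layer, which maps them to exit code 2) can catch one
base type.
"""


class HkmetaError(Exception):
    """Base class for all hkmeta errors."""


class InvalidInputError(HkmetaError, ValueError):
    """Malformed or out-of-domain input (bad counts, non-finite values...)."""


class InsufficientDataError(HkmetaError, ValueError):
    """Fewer studies than the requested analysis needs."""


class DegreesOfFreedomError(HkmetaError, ValueError):
    """Residual degrees of freedom would be non-positive (n <= p)."""


class SingularDesignError(HkmetaError, ValueError):
    """Design matrix is rank deficient."""
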