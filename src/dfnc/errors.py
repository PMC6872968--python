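"""Exception types shared across pipeline stages."""


class DFNCError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(DFNCError, ValueError):
    """A configuration value is outside its documented range."""


class ConformabilityError(DFNCError, ValueError):
    """Array shapes do not conform for the requested operation."""


class DecompositionError(DFNCError, RuntimeError):
    """A matrix factorization (Cholesky, PCA, ICA) failed."""


class InvalidInputError(DFNCError, ValueError):
    """Input data violate an operation's preconditions."""
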