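"""Exception hierarchy used across the package."""


class SemforageError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SemforageError):
    """A file does not conform to its declared format (missing column, bad header...)."""


class DataError(SemforageError):
    """The data are well-formed but violate a contract (negative IRT, missing label...)."""


class NumericError(SemforageError):
    """A numeric degeneracy that the caller must resolve (zero-norm vector...)."""


class DegenerateTestError(SemforageError):
    """A statistical test cannot be computed (all paired differences zero...)."""
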