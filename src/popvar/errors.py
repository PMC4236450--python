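"""Exception and warning types shared across the package."""


class PopvarError(Exception):
    """Base class for all package-specific errors."""


class VcfFormatError(PopvarError, ValueError):
    """Malformed or unsupported VCF content (names the offending record)."""


class SampleLookupError(PopvarError, KeyError):
    """A requested sample or population is absent from the data."""


class ContractError(PopvarError, ValueError):
    """A precondition of an operation was violated by the caller."""


class DegenerateDataWarning(UserWarning):
    """Emitted when an operation proceeds on degenerate input (all-missing
    genotypes, zero-variance columns, empty filter results)."""
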