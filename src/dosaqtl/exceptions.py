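"""Exception types shared across the toolkit."""


class DosaqtlError(Exception):
    """Base class for all package-specific errors."""


class MonomorphicError(DosaqtlError):
    """A variant with no variation where a polymorphic one is required."""


class CapacityError(DosaqtlError):
    """A haplotype pool too small for the requested cohort."""


class VcfFormatError(DosaqtlError):
    """A VCF that cannot be interpreted as a dosage call set."""


class CollinearityError(DosaqtlError):
    """A rank-deficient design matrix; names the offending columns."""


class EmptyCallSetError(DosaqtlError):
    """A call-set comparison whose denominator is empty after filtering."""
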