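"""Exception hierarchy shared across the package."""


class AmplicloneError(Exception):
    """Base class for all package errors."""


class DomainError(AmplicloneError, ValueError):
    """An argument is outside the domain an operation is defined on
    (coordinate off the amplicon, protospacer index out of 1-20, ...)."""


class ValidationError(AmplicloneError, ValueError):
    """A composite input violates an invariant (haplotype weights not
    summing to one, mixed references in a matrix, unknown sample id)."""


class EmptySampleError(AmplicloneError):
    """Raised when a sample yields zero mapped fragments: the sample is
    reported explicitly rather than silently producing an empty pileup."""


class NoCallError(AmplicloneError):
    """Raised when a clone cannot be genotyped (zero depth at the target)."""


class NoPhaseError(AmplicloneError):
    """Raised when phasing finds zero informative fragments."""
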