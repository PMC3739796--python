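"""Exception hierarchy shared across the package."""


class CytophyloError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CytophyloError):
    """Malformed input text (duplicate labels, empty arrangement, bad TSV row)."""


class ComparabilityError(CytophyloError):
    """Two segment orders do not share the same label set / arm."""


class WindowError(CytophyloError):
    """A reversal window violates its bounds or minimum length."""


class NoDifferenceError(CytophyloError):
    """Window inference requested between two identical orders."""


class NotOneStepError(CytophyloError):
    """No single reversal transforms the reference into the derived order."""


class CapExceededError(CytophyloError):
    """Arrangement length or search depth exceeds the configured cap."""


class EmptySampleError(CytophyloError):
    """A statistic was requested on zero observations."""


class MonomorphicError(CytophyloError):
    """HWE testing requested on a monomorphic genotype sample."""


class UndefinedPercentageError(CytophyloError):
    """Co-carriage percentage undefined because no larva carries either locus."""


class InconsistencyError(CytophyloError):
    """Summary counts violate inclusion-exclusion constraints."""


class RegistryError(CytophyloError):
    """A rearrangement id fails to resolve in the registry."""


class SimulationSpecError(CytophyloError):
    """Invalid simulation specification (frequency/rate out of range, etc.)."""


class SexDataUnavailableError(CytophyloError):
    """Sex-linkage analysis requested but larval sexes are missing."""
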