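"""Exception hierarchy used across the package."""


class RecmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RecmapError):
    """A configuration value is invalid; the message names the field."""


class InputError(RecmapError):
    """Inputs violate a precondition (overlapping groups, misaligned ids...)."""


class DimensionError(RecmapError):
    """Arrays or tables that must be aligned have incompatible shapes."""


class PedigreeError(RecmapError):
    """Pedigree is malformed (cycle, missing parent record, bad ordering)."""


class SampleLookupError(RecmapError):
    """A referenced sample id is absent from the dataset."""


class AllFilteredError(RecmapError):
    """Quality control removed every individual or every marker."""


class NumericalError(RecmapError):
    """A numerical routine failed (e.g. relationship matrix far from PSD)."""


class ContractError(RecmapError):
    """An operation was called outside its contract (e.g. truncation length
    requested for a variant that is not a stop-gain)."""


class ReferenceMismatchError(RecmapError):
    """The declared reference allele disagrees with the reference sequence."""


class DependencyError(RecmapError):
    """A pipeline stage is missing an upstream artifact; names the stage."""
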