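"""Exception hierarchy shared across the package."""


class NbstratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NbstratError, ValueError):
    """A file does not conform to the expected layout (names the offending cell)."""


class ValidationError(NbstratError, ValueError):
    """A value violates a documented invariant (negative time, bad event code, ...)."""


class HarmonizationError(NbstratError, ValueError):
    """Cross-cohort gene harmonization cannot proceed (e.g. empty intersection)."""


class SampleLookupError(NbstratError, KeyError):
    """Referenced sample identifiers are absent from the dataset."""


class ParameterError(NbstratError, ValueError):
    """An algorithm parameter is out of its admissible range."""


class AssignmentError(NbstratError, ValueError):
    """A cluster assignment is invalid for the requested operation."""


class DegenerateDataError(NbstratError, ValueError):
    """The input is degenerate for the requested fit (no events, zero variance, ...)."""


class UndefinedIndexError(NbstratError, ValueError):
    """A validity index is undefined for the given partition (e.g. single cluster)."""


class FitError(NbstratError, RuntimeError):
    """A model fit failed irrecoverably."""
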