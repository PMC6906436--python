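"""Exception hierarchy.

Everything user-facing derives from :class:`GetPCRError`; input problems derive
from :class:`ValidationError` so the CLI can map them to exit code 2.
"""


class GetPCRError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GetPCRError, ValueError):
    """Invalid user input (sequences, tables, configuration)."""


class GuideNotFoundError(ValidationError):
    """The protospacer/PAM combination occurs nowhere on either strand."""


class AmbiguousGuideError(ValidationError):
    """The protospacer/PAM combination occurs more than once."""


class UnsupportedEditError(ValidationError):
    """An edit kind not handled by the requested operation (e.g. a deletion
    passed to the variant-primer designer, which needs substitutions)."""


class UndesignableLocusError(GetPCRError):
    """No primer candidate reaches the Tm window within the length cap."""


class UndesignableControlError(UndesignableLocusError):
    """The locus cannot accommodate a control amplicon."""


class AmbiguousAnchorError(ValidationError):
    """A primer's 5' anchor occurs more than once in the template."""


class UndefinedPenaltyError(GetPCRError):
    """Penalty requested for an unanchored mismatch profile."""


class HighFidelityModeError(GetPCRError):
    """A proofreading-polymerase penalty model was handed to a pipeline that
    relies on 3'-mismatch discrimination."""


class IncompleteAssayError(ValidationError):
    """A Ct-table slice is missing a required channel or is empty."""


class InsufficientReplicatesError(ValidationError):
    """Fewer replicates than the statistical test requires."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested for a zero-variance vector."""


class InconsistentAssayError(ValidationError):
    """Per-base allele fractions sum to more than one."""


class SchemaError(ValidationError):
    """A delimited input file does not match the expected schema."""
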