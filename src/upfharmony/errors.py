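"""Exception hierarchy shared across the pipeline stages."""


class UpfHarmonyError(Exception):
    """Base class for all package errors."""


class ValidationError(UpfHarmonyError, ValueError):
    """Input fails a structural or semantic check."""


class FormatError(ValidationError):
    """A file does not have the expected layout (e.g. missing column)."""


class IntegrityError(ValidationError):
    """Cross-record consistency violated (e.g. duplicate identifiers)."""


class MissingItemError(ValidationError):
    """A consumed food item is absent from a lookup table."""


class DomainError(UpfHarmonyError, ValueError):
    """A numeric argument lies outside the formula's domain."""


class InsufficientDataError(UpfHarmonyError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(UpfHarmonyError, ValueError):
    """Data admit no informative answer (constant input, singular design)."""


class UnknownSystemError(UpfHarmonyError, KeyError):
    """Classification system name is not one of NOVA, IARC, IFIC, UNC."""
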