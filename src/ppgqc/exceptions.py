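"""Error taxonomy shared across the pipeline."""


class PpgqcError(Exception):
    """Base class for all package errors."""


class FormatError(PpgqcError):
    """A file does not parse under the declared dialect."""


class IntegrityError(PpgqcError):
    """Data violates a structural invariant (lengths, ordering, coverage)."""


class ParameterError(PpgqcError, ValueError):
    """An argument is outside its admissible domain."""


class DegeneratePulseError(PpgqcError):
    """A pulse has zero variance and cannot be normalized; callers drop it."""


class TransformError(PpgqcError):
    """A feature-conditioning transform cannot be fitted."""


class OptimizationError(PpgqcError):
    """An optimizer produced a non-finite objective."""


class TaskError(PpgqcError):
    """A classification task cannot be formed (e.g. single-class input)."""


class ConfigurationError(PpgqcError):
    """The run configuration is inconsistent with the data."""


class UndefinedAgreementError(PpgqcError):
    """Chance agreement equals one; the agreement statistic is undefined."""
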