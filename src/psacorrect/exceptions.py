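"""Exception hierarchy for psacorrect."""


class PsaCorrectError(Exception):
    """Base class for all package errors."""


class SchemaError(PsaCorrectError):
    """A required column/role is missing or mis-declared in an input table."""


class ValidationError(PsaCorrectError):
    """A value violates a domain invariant (e.g. dosage outside {0, 1, 2})."""


class ClassificationError(PsaCorrectError):
    """Risk classification is impossible (Gleason and stage both missing)."""


class ConfigError(PsaCorrectError):
    """A simulation or analysis configuration value is out of range."""


class DataError(PsaCorrectError):
    """Input data violate an assumption the method relies on
    (e.g. dosage 0 at a locus scored with the shifted-additive contrast)."""


class SeparationError(PsaCorrectError):
    """Logistic fit suffers (quasi-)complete separation; no trustworthy estimate."""
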