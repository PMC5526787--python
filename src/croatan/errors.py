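"""Exception hierarchy shared across the toolkit."""


class CroatanError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CroatanError):
    """An input file violates its declared format."""


class ValidationError(CroatanError):
    """Input is well-formed but semantically invalid."""


class ConfigError(CroatanError):
    """A configuration value violates an invariant."""


class FitError(CroatanError):
    """A model could not be fitted (e.g. rank-deficient design)."""


class TrainingError(CroatanError):
    """Classifier training is impossible on the given data."""


class PairingError(CroatanError):
    """Guide pairing cannot proceed (too few guides, exhausted barcodes...)."""


class EmptyResultError(CroatanError):
    """An operation filtered away every record."""
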