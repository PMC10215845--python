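"""Exception hierarchy for the mhdnet pipeline."""


class MhdnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MhdnetError):
    """A signal or header file is malformed or uses an unsupported layout."""


class AnnotationError(MhdnetError):
    """An annotation stream is missing or contains no beat annotations."""


class ConfigurationError(MhdnetError):
    """A run or dataset configuration is inconsistent or unsatisfiable."""


class ContractError(MhdnetError):
    """Shapes or values passed between pipeline stages violate a contract."""


class LeakageError(MhdnetError):
    """Train/validation/test sets share a subject."""
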