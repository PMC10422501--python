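"""Exception hierarchy shared across the pipeline stages."""


class EgopoolError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EgopoolError, ValueError):
    """A tabular input or config file is missing or misusing a declared field."""


class ValidationError(EgopoolError, ValueError):
    """Input content violates an invariant (duplicate ids, empty manifest, ...)."""


class ParameterError(EgopoolError, ValueError):
    """An argument is outside its documented domain."""


class DataError(EgopoolError, ValueError):
    """Array content is invalid (non-finite values, wrong dtype family)."""


class StateError(EgopoolError, RuntimeError):
    """An object was used before being initialised."""


class TrainingError(EgopoolError, RuntimeError):
    """Classifier training preconditions are not met."""


class EmptyClipError(EgopoolError, OSError):
    """A clip source yielded zero decodable frames."""
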