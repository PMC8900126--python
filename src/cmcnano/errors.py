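"""Exception hierarchy."""


class CmcnanoError(Exception):
    """Base class for package errors."""


class ConfigurationError(CmcnanoError):
    """Invalid configuration value (unknown convention, rule, format, ...)."""


class FitError(CmcnanoError):
    """Constrained distribution fit failed; carries the residual report."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class EmbeddingError(CmcnanoError):
    """Self-avoiding embedding failed after the retry budget."""

    def __init__(self, message, retries=None):
        super().__init__(message)
        self.retries = retries


class EstimationError(CmcnanoError):
    """Statistical estimator could not produce a value."""


class PackingError(CmcnanoError):
    """Rejection packing exhausted its attempt budget."""

    def __init__(self, message, achieved=None):
        super().__init__(message)
        self.achieved = achieved


class SchemaError(CmcnanoError):
    """File failed schema validation; message names the offending row/field."""


class ParallelSegmentsError(CmcnanoError):
    """Two-line fit produced (near-)parallel segments; no intersection."""


class OutOfModelError(CmcnanoError):
    """Measured value falls outside the invertible range of the model."""
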