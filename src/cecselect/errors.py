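"""Exception hierarchy shared across the pipeline."""


class CecselectError(Exception):
    """Base class for all package errors."""


class SchemaError(CecselectError):
    """An input file does not have the required columns/layout."""


class ValidationError(CecselectError):
    """Data violate an invariant of the study data model."""


class ConfigurationError(CecselectError):
    """A run or simulation configuration is infeasible or incomplete."""


class ConvergenceError(CecselectError):
    """An iterative fit failed to converge within its iteration budget."""
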