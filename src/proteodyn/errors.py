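"""Exception hierarchy shared by all proteodyn modules."""


class ProteodynError(Exception):
    """Base class for all package errors."""


class FormatError(ProteodynError):
    """A tabular input file does not have the expected columns/layout."""


class ValidationError(ProteodynError):
    """Structurally well-formed input violates a model invariant."""


class ParameterError(ProteodynError):
    """A parameter value is outside its admissible range."""


class ConfigurationError(ProteodynError):
    """A configuration entry cannot be resolved (e.g. unknown region name)."""


class NumericalError(ProteodynError):
    """An integrator failed to meet its tolerances."""


class AssumptionViolationError(ProteodynError):
    """A runtime check of a mathematical assumption failed (e.g. theta' <= 0)."""
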