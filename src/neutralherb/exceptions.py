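"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DomainError(ValueError):
    """A function argument is outside the function's domain."""


class DataError(ValueError):
    """Observed data violate the model's support or schema."""


class ComparisonError(ValueError):
    """Two fits are not comparable (different data or conventions)."""
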