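"""Exception hierarchy for the pipeline."""


class StroopMultiverseError(Exception):
    """Base class for all package errors."""


class SchemaError(StroopMultiverseError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(StroopMultiverseError):
    """A row or field violates a documented invariant."""


class ParameterError(StroopMultiverseError):
    """An operator or generator received invalid parameters."""
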