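"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration value (unknown group, non-positive variance, ...)."""


class CapacityError(RuntimeError):
    """A generator could not place the requested number of items within budget."""


class ValidationError(ValueError):
    """Input data violates a structural contract (duplicate barcodes, bad pair table, ...)."""


class DataError(ValueError):
    """Fatal data problem (e.g. spike-in count of zero at the reference timepoint)."""


class SchemaError(ValueError):
    """Feature-schema mismatch between producer and consumer."""


class ParseError(ValueError):
    """Malformed record in a sequencing file; carries the 1-based record number."""

    def __init__(self, message: str, record_number: int | None = None):
        super().__init__(message)
        self.record_number = record_number
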