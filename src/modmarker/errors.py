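"""Exception hierarchy shared across the package."""


class ModMarkerError(Exception):
    """Base class for all modmarker errors."""


class SchemaError(ModMarkerError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(ModMarkerError):
    """Data violates a domain invariant (range, uniqueness, consistency)."""


class GeneLookupError(ModMarkerError, KeyError):
    """A requested gene (or cohort) is absent from the dataset."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain text
        return Exception.__str__(self)
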