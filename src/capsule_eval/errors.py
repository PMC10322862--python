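"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input record, parameter or schema fails validation.

    The message always names the offending field (and row, where rows
    exist) so pipeline failures are auditable.
    """


class UndefinedAlphaError(ValueError):
    """Raised when Krippendorff's alpha is undefined for the given data
    (no item carries two or more non-missing values)."""
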