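"""Exception types shared across the package."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but statistically degenerate
    (zero IQR, constant profile, undefined correlation...)."""


class MissingDataError(ValueError):
    """Raised when required observations are absent (e.g. an empty parcel)."""
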