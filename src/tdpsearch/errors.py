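"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """An input file could not be parsed."""


class ConfigurationError(ValueError):
    """Invalid or incomplete search configuration."""


class EmptyDatabaseError(ValueError):
    """The protein database is empty after loading/sanitization."""


class ProteoformError(ValueError):
    """A proteoform is structurally invalid (e.g. empty after truncation)."""
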