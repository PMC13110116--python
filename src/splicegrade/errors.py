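"""Exception hierarchy shared across the pipeline."""


class SplicegradeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SplicegradeError):
    """A file does not conform to its expected dialect (missing columns, bad header)."""


class ValidationError(SplicegradeError):
    """Input values violate a contract (negative abundances, orphan transcripts...)."""


class ConfigError(SplicegradeError):
    """A configuration value is out of range or inconsistent."""


class DegenerateDataError(SplicegradeError):
    """Data are degenerate for the requested computation (empty library, no shared genes)."""
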