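"""Exception hierarchy shared across the pipeline."""


class BerryroadError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(BerryroadError):
    """A cohort configuration field is invalid; message names the field."""


class InputError(BerryroadError):
    """Malformed or inconsistent input data."""


class DegenerateCurveError(InputError):
    """A compression curve has no usable peak structure."""
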