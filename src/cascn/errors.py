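"""Exception hierarchy for the cascn pipeline."""


class CascnError(Exception):
    """Base class for all cascn errors."""


class FormatError(CascnError):
    """An input file violates the expected on-disk format (grid/affine mismatch, ...)."""


class SchemaError(CascnError):
    """A participants table is missing required columns or violates field constraints."""


class ConfigurationError(CascnError):
    """A run configuration or seed/region specification is invalid."""


class StagingError(CascnError):
    """Severity staging produced a stage too small for a group comparison."""


class DesignError(CascnError):
    """A regression design matrix is rank deficient or otherwise unusable."""


class DegenerateInputError(CascnError):
    """A series or map is constant/empty where variation is required."""
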