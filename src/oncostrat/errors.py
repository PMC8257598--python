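"""Exception hierarchy shared across the pipeline."""


class OncostratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OncostratError):
    """A file does not conform to the expected text format."""


class ValidationError(OncostratError):
    """Inputs violate a documented precondition."""


class DegenerateDataError(OncostratError):
    """Data are too degenerate for the requested statistic (e.g. a constant
    marker gene, an empty gene-set overlap, zero variance everywhere)."""
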