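"""Exception hierarchy shared across the package."""


class H2OPETError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(H2OPETError, ValueError):
    """A model or configuration parameter is out of its admissible range."""


class DomainError(H2OPETError, ValueError):
    """An evaluation point lies outside the supported time/space window."""


class DegenerateInputError(H2OPETError, ValueError):
    """Input is structurally valid but carries no usable signal (all-zero image,
    empty mask, fully-cropped VOI, ...)."""


class SchemaError(H2OPETError, ValueError):
    """A table or config is missing required columns/keys; the message lists them."""


class GridMismatchError(H2OPETError, ValueError):
    """Two objects that must share a sampling grid (schedule, basis, image) do not."""
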