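"""Exception types shared across the package."""


class ReefpopError(Exception):
    """Base class for all package errors."""


class DimensionError(ReefpopError, ValueError):
    """Input arrays have incompatible shapes or lengths."""


class SampleSizeError(ReefpopError, ValueError):
    """Too few sequences / individuals for the requested statistic."""


class UndefinedStatisticError(ReefpopError, ValueError):
    """Statistic is undefined for this input (e.g. no segregating sites)."""


class DegenerateInputError(ReefpopError, ValueError):
    """Input is degenerate (constant vector, empty graph, all-land raster...)."""


class ConfigError(ReefpopError, ValueError):
    """Invalid configuration or prior specification."""
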