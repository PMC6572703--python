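"""Exception hierarchy shared across the pipeline stages."""


class OneBoxError(Exception):
    """Base class for all package-specific errors."""


class GridError(OneBoxError, ValueError):
    """Time grids are irregular or do not match between inputs."""


class ConfigurationError(OneBoxError, ValueError):
    """A scenario or run configuration is inconsistent or incomplete."""


class DomainError(OneBoxError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class EstimationError(OneBoxError, RuntimeError):
    """An estimator has no usable data (e.g. no activity-labeled steps)."""


class FormatError(OneBoxError, ValueError):
    """An instrument log or results file could not be parsed."""


class DataError(OneBoxError, ValueError):
    """Data are parseable but unusable (e.g. gaps exceed the fill limit)."""
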