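"""Exception hierarchy used across the package."""


class EhrMtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EhrMtlError, ValueError):
    """An input configuration violates its contract (bad probability, empty set, ...)."""


class DegenerateLabelsError(EhrMtlError, ValueError):
    """A training target contains a single class and cannot be fit or scored."""


class InsufficientTasksError(EhrMtlError, ValueError):
    """Fewer eligible auxiliary tasks than the largest requested set size."""


class StratificationError(EhrMtlError, ValueError):
    """Too few positive cases to form stratified train/validation/test splits."""


class InsufficientDataError(EhrMtlError, ValueError):
    """A histogram or report was requested on an empty case or control set."""


class UndefinedMetricError(EhrMtlError, ValueError):
    """A ranking metric was requested on single-class labels."""
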