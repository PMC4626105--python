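"""Exception taxonomy shared across the package."""


class ConeKineticsError(Exception):
    """Base class for all package errors."""


class ParameterError(ConeKineticsError, ValueError):
    """A parameter is outside its physical or numerical domain."""


class AccuracyError(ConeKineticsError, ValueError):
    """A grid is too coarse for the requested delay to be resolved reliably."""


class FormatError(ConeKineticsError, ValueError):
    """A trace file or config is malformed."""


class FitError(ConeKineticsError, RuntimeError):
    """A fit cannot be set up (e.g. too few points in the fit segment)."""


class ClassificationError(ConeKineticsError, RuntimeError):
    """A recovery phase cannot be classified (e.g. no detectable peak)."""


class MetricError(ConeKineticsError, RuntimeError):
    """A requested metric is undefined for the given classification."""
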