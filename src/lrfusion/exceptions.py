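"""Exception hierarchy shared by all lrfusion modules."""


class LRFusionError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LRFusionError, ValueError):
    """A configuration object or argument is out of its valid range."""


class ShapeError(LRFusionError, ValueError):
    """Array dimensions do not match what a fitted model expects."""


class DegenerateDataError(LRFusionError, ValueError):
    """Data carry no usable variation (constant column, zero spread)."""


class DegenerateLabelsError(DegenerateDataError):
    """Only one class present where a two-class fit is required."""


class CollinearityError(LRFusionError, ValueError):
    """Design matrix is rank-deficient (e.g. constant column plus intercept)."""


class DataLeakageError(LRFusionError, ValueError):
    """The same rows appear in partitions that must be disjoint."""


class StratificationError(LRFusionError, ValueError):
    """A stratified split cannot place both classes in every partition."""


class ConvergenceError(LRFusionError, RuntimeError):
    """An iterative fit failed beyond the tolerated amount."""
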