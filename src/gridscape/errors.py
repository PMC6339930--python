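"""Exception types shared across gridscape modules."""


class GridscapeError(Exception):
    """Base class for all gridscape errors."""


class InvalidShapeError(GridscapeError):
    """Arena construction parameters do not describe a valid shape."""


class InvalidTransformError(GridscapeError):
    """Transforming-arena schedule is inconsistent (e.g. end shape not square)."""


class OutsideArenaError(GridscapeError):
    """A query point lies outside the arena."""


class DegenerateArenaError(GridscapeError):
    """Arena too small to support a foraging step."""


class InvalidTrainingError(GridscapeError):
    """Training hyper-parameters are invalid (e.g. non-positive epochs)."""


class InsufficientSamplingError(GridscapeError):
    """A map region has too few trajectory samples to analyse."""


class UndefinedEllipseError(GridscapeError):
    """Fewer than three autocorrelogram peaks; ellipse fit undefined."""


class DegenerateRegressionError(GridscapeError):
    """Regression input has fewer than three points or constant abscissa."""


class DegenerateLabelsError(GridscapeError):
    """Classifier training set contains a single class."""


class EmptyInputError(GridscapeError):
    """An operation received an empty array where data was required."""
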