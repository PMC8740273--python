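"""Exception and warning types shared across the pipeline."""


class DrpipeError(Exception):
    """Base class for all drpipe errors."""


class AllDarkImage(DrpipeError):
    """Every pixel of the image is below the dark-border threshold."""


class NotSquare(DrpipeError):
    """Operation requires a square (H == W) image."""


class InvalidCounts(DrpipeError):
    """Class counts incompatible with the balancing formula."""


class MissingClass(DrpipeError):
    """A class has zero examples where every class is required."""


class BadLabel(DrpipeError):
    """A manifest label is outside the valid grade range 0-4."""


class MissingFile(DrpipeError):
    """A manifest references an image file that does not exist."""


class UnknownBackbone(DrpipeError):
    """Requested backbone name is not in the registry."""


class BackboneUnavailable(DrpipeError):
    """Backbone is registered by name but no implementation is installed."""


class EmptyDataset(DrpipeError):
    """Training requires a non-empty dataset."""


class AllZeroF1(DrpipeError):
    """All classifier F1 scores are zero; fusion weights are undefined."""


class ShapeMismatch(DrpipeError):
    """Probability matrices disagree in shape or count."""


class LengthMismatch(DrpipeError):
    """Label and prediction vectors differ in length."""


class EmptyClass(DrpipeError):
    """A true class with zero samples makes ACA undefined."""


class DegenerateClass(DrpipeError):
    """A class with no positives or no negatives makes AUC undefined."""


class ConfigError(DrpipeError):
    """Pipeline configuration failed validation."""


class NegativeLambdaWarning(UserWarning):
    """A fusion weight went negative (large amplification n)."""
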