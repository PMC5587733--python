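"""Exception hierarchy shared across the package."""


class DeepFlowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DeepFlowError):
    """Invalid or inconsistent configuration."""


class ManifestError(DeepFlowError):
    """Malformed manifest table."""


class ImageLoadError(DeepFlowError):
    """An image file referenced by the manifest could not be read."""


class ImageFormatError(DeepFlowError):
    """An image file is readable but not a 2-D single-channel image."""


class ValidationError(DeepFlowError):
    """An in-memory object violates its invariants."""


class StratificationError(DeepFlowError):
    """A class is too small to be split across the requested folds."""


class TrainingDivergedError(DeepFlowError):
    """Non-finite loss encountered during optimisation."""

    def __init__(self, epoch: int, batch: int, lr: float):
        self.epoch, self.batch, self.lr = epoch, batch, lr
        super().__init__(
            f"non-finite loss at epoch {epoch}, batch {batch} (learning rate {lr:g})"
        )


class ParameterError(DeepFlowError):
    """A numeric parameter is outside its valid range."""


class DegenerateGeometryError(DeepFlowError):
    """Input geometry carries no usable structure (e.g. all points identical)."""
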