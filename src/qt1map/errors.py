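"""Exception hierarchy shared across the pipeline."""


class QT1Error(Exception):
    """Base class for all qt1map errors."""


class ParameterError(QT1Error, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(QT1Error, ValueError):
    """A phantom or pipeline configuration is internally inconsistent."""


class GridMismatchError(QT1Error, ValueError):
    """Volumes that must share a grid (shape + affine) do not."""


class SeedError(QT1Error, ValueError):
    """A region-growing seed voxel fails the inclusion predicate."""


class AnalysisError(QT1Error, RuntimeError):
    """A statistical stage cannot proceed (e.g. one-class input, empty mask)."""


class VolumeIOError(QT1Error, OSError):
    """A volume file is missing or not a readable NIfTI payload."""
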