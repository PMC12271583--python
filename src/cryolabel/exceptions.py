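"""Exception and warning types shared across the package."""


class CryolabelError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CryolabelError, ValueError):
    """A parameter is outside its valid domain (non-positive voxel size, ...)."""


class GridBoundsError(CryolabelError, IndexError):
    """A grid index lies outside the owning grid's dimensions."""


class MapFormatError(CryolabelError, ValueError):
    """An MRC file violates the MRC2014 format; the message names the field."""


class EmptyStructureError(CryolabelError, ValueError):
    """An atomic structure contains no atoms after filtering."""


class AlignmentError(CryolabelError, ValueError):
    """Two grids (or a grid and a structure) do not share compatible geometry."""


class PipelineError(CryolabelError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


class UndersampledKernelWarning(UserWarning):
    """Kernel sigma is below half the voxel size; the Gaussian is undersampled."""


class EmptyLabelWarning(UserWarning):
    """No atom passed dual validation; the label maps are all zero."""
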