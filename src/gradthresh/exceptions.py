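"""Exception types raised by gradthresh."""


class GradthreshError(Exception):
    """Base class for all package errors."""


class ParameterError(GradthreshError, ValueError):
    """An argument is outside its documented domain."""


class NoPhaseError(GradthreshError, RuntimeError):
    """No threshold level produced a non-empty phase boundary."""


class ImageFormatError(GradthreshError, ValueError):
    """An input file is not a single-channel 8/16-bit raster."""


class ScenePackingError(GradthreshError, RuntimeError):
    """Requested synthetic objects cannot be placed without overlap."""
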