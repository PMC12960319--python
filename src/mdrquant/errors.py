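"""Domain-specific exceptions.

Plain ``ValueError`` is used for ordinary argument validation; the classes
here mark conditions a caller may want to catch and handle specially
(skip an image, regenerate a phantom, ...).
"""


class MdrQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MdrQuantError, ValueError):
    """Invalid configuration, e.g. image dimensions not divisible by the
    segmenter's downsampling factor."""


class DegeneratePhantomError(MdrQuantError, ValueError):
    """Requested phantom geometry rasterizes to an unusably small region."""


class EmptyRegionError(MdrQuantError, ValueError):
    """A tissue region required by a computation has no pixels."""


class ShapeError(MdrQuantError, ValueError):
    """Image/mask shape mismatch or wrong input size for a model."""


class MaskFormatError(MdrQuantError, ValueError):
    """A mask file contains values outside the label palette {0,1,2,3}."""


class DataError(MdrQuantError, ValueError):
    """Empty or structurally invalid data set."""
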