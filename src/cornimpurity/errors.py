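"""Exception hierarchy shared by all pipeline stages."""


class CornImpurityError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CornImpurityError, ValueError):
    """A file decoded, but its payload violates the expected raster format."""


class ParameterError(CornImpurityError, ValueError):
    """A configuration or function parameter violates its contract."""


class DegenerateImageError(CornImpurityError, ValueError):
    """The image carries too little information for the operation (e.g. a
    single gray level, which cannot be thresholded)."""
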