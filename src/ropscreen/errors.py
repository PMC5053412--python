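"""Exception types raised by the pipeline."""


class RopscreenError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(RopscreenError, ValueError):
    """An input carries no usable signal (constant image, empty mask, ...)."""


class SizingError(RopscreenError, ValueError):
    """Image geometry cannot accommodate the requested anatomy/regions."""
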