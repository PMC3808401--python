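"""Exception hierarchy shared across the pipeline stages."""


class FinstripeError(Exception):
    """Base class for all finstripe errors."""


class EmptyForegroundError(FinstripeError):
    """An operation that needs foreground pixels received none."""


class SegmentationError(FinstripeError):
    """Background removal produced no usable foreground."""


class DegeneratePaletteError(FinstripeError):
    """Palette has no second color, so the color ratio is undefined."""


class TPSFormatError(FinstripeError):
    """A TPS landmark file violates the expected dialect."""


class SaturationError(FinstripeError):
    """Sequence divergence too large for the K2P log corrections."""


class LabelMismatchError(FinstripeError):
    """Two labelled containers disagree on specimen or class labels."""
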