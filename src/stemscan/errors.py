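"""Exception types shared across the pipeline."""


class StemscanError(Exception):
    """Base class for all package errors."""


class EmptyCloudError(StemscanError):
    """Raised when no valid return survives record validation."""


class DegenerateFitError(StemscanError):
    """Circle fit attempted on fewer than 3 points or a collinear set."""


class NoGroundError(StemscanError):
    """RANSAC consensus below the minimum inlier fraction, or the fitted
    plane is too steep to be ground."""


class SchemaError(StemscanError):
    """A CSV table is missing required columns or holds non-numeric cells."""
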