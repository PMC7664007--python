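"""Exception hierarchy shared across the pipeline stages."""


class IppkitError(Exception):
    """Base class for all ippkit errors."""


class InvalidInputError(IppkitError, ValueError):
    """An argument violates a documented precondition."""


class CoRegistrationError(IppkitError):
    """Rasters that must share a pixel grid do not."""

    def __init__(self, raster_name: str, detail: str = ""):
        self.raster_name = raster_name
        msg = f"raster {raster_name!r} is not co-registered with the orthomosaic"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class EmptyTileError(IppkitError):
    """A plot window contains no usable pixels."""


class EmptyMaskError(IppkitError):
    """An operation that requires plant pixels received an empty mask."""


class InvalidShiftError(InvalidInputError):
    """Requested outline slide magnitude is >= the vector length."""


class InvalidMatrixError(InvalidInputError):
    """A distance matrix is not symmetric / square / zero-diagonal."""


class UndefinedMetricError(IppkitError):
    """A metric is undefined for the given inputs (e.g. two empty masks)."""
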