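"""Exception hierarchy for spacol.

Every error raised by the package derives from :class:`SpacolError`, so callers
can catch one type. The finer-grained subclasses mirror the failure modes of
the pipeline stages: bad reference data, degenerate numerics, malformed files,
and statistical designs that cannot be analysed.
"""


class SpacolError(Exception):
    """Base class for all spacol errors."""


class SpectrumLoadError(SpacolError):
    """A packaged or user-supplied spectrum file is missing or malformed."""


class SpectrumValidationError(SpacolError):
    """A spectrum violates its invariants (coverage, monotonicity, sign)."""


class DegenerateSpectrumError(SpacolError):
    """Min-max normalization attempted on a spectrum constant over the window."""


class IdentifiabilityError(SpacolError):
    """The unmixing design matrix is rank deficient (collinear chromophores)."""


class WavelengthRangeError(SpacolError):
    """A requested wavelength falls outside a spectrum's tabulated coverage."""


class FluenceError(SpacolError):
    """Missing or zero fluence for a wavelength that must be normalized."""


class StackStateError(SpacolError):
    """A stack operation applied in the wrong normalization state."""


class StackFormatError(SpacolError):
    """An image stack on disk disagrees with its metadata sidecar."""


class AnnotationError(SpacolError):
    """An ROI polygon is invalid (too few vertices, self-intersecting, ...)."""


class VocabularyError(SpacolError):
    """An organ label outside the controlled vocabulary."""


class EmptyRoiError(SpacolError):
    """An ROI contains no eligible (non-degenerate) pixels."""


class StainMatrixError(SpacolError):
    """A stain matrix is singular or otherwise unusable."""


class EmptyMaskError(SpacolError):
    """A tissue mask with no foreground pixels."""


class SampleSizeError(SpacolError):
    """Too few observations for the requested statistic."""


class DegenerateFitError(SpacolError):
    """A regression or test with zero variance in a required direction."""


class DesignError(SpacolError):
    """A factorial design that cannot support the requested decomposition."""


class SpecificationError(SpacolError):
    """A synthetic-data specification violates its invariants."""
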