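"""Exception hierarchy shared across the package.

Feature-level failures derive from :class:`FeatureUnavailable`; the feature
assembly step converts them into masked (missing) entries rather than
aborting, because a single degenerate trace must not sink a whole dataset.
Everything else derives from :class:`PeakQCError` and is a hard error.
"""


class PeakQCError(Exception):
    """Base class for all errors raised by peakqc."""


# --- hard errors -----------------------------------------------------------

class EmptyPeakRegion(PeakQCError):
    """No sampled time point falls inside the peak boundaries."""


class MissingColumn(PeakQCError):
    def __init__(self, column: str, path: str = ""):
        self.column = column
        super().__init__(f"required column {column!r} missing" + (f" in {path}" if path else ""))


class RaggedVectors(PeakQCError):
    """Times and intensities of a chromatogram row decode to different lengths."""


class UnparseableNumber(PeakQCError):
    pass


class InvalidBoundary(PeakQCError):
    """Peak boundary with start >= end."""


class KeyCollision(PeakQCError):
    """Two chromatogram rows decode to the same transition key."""


class EmptyResult(PeakQCError):
    """A merge/filter step left no usable rows."""


class InvalidStatus(PeakQCError):
    """Annotation status outside the binary ok/flag vocabulary."""


class IncompletePair(PeakQCError):
    """A transition pair is missing one of its isotope labels."""


class SingleClass(PeakQCError):
    """Training or evaluation requires both ok and flag examples."""


class SchemaMismatch(PeakQCError):
    """Feature names/order at prediction time differ from training time."""


class CountExceedsRuns(PeakQCError):
    """Learning-curve run count larger than the number of available runs."""


class UnknownDefect(PeakQCError):
    pass


class InvalidConfig(PeakQCError):
    pass


# --- recoverable feature failures ------------------------------------------

class FeatureUnavailable(PeakQCError):
    """A QC feature cannot be computed on this input; carried as missing."""


class TooFewPoints(FeatureUnavailable):
    pass


class ConstantTrace(FeatureUnavailable):
    pass


class ConstantHalf(FeatureUnavailable):
    pass


class ZeroPeak(FeatureUnavailable):
    pass


class SingletonGroup(FeatureUnavailable):
    pass


class ZeroDenominator(FeatureUnavailable):
    pass
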