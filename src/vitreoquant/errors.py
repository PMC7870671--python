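"""Exception and warning hierarchy for vitreoquant."""


class VitreoquantError(Exception):
    """Base class for all vitreoquant errors."""


class FormatError(VitreoquantError):
    """On-disk data is missing or not in the expected format."""


class ConsistencyError(VitreoquantError):
    """Sidecar metadata and image files disagree."""


class ValidationError(VitreoquantError):
    """An input value violates a documented invariant."""


class SegmentationError(VitreoquantError):
    """Retinal boundary detection failed on too many columns.

    Carries a ``diagnostics`` dict (counts of invalid columns and the
    reasons) to make failures debuggable.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedScoreError(VitreoquantError):
    """The VI ratio is undefined (non-positive RPE signal)."""


class GatedVolumeError(VitreoquantError):
    """The volume failed the image-quality gate."""


class InsufficientDataError(VitreoquantError):
    """Too few observations remain for the requested statistic."""


class UndefinedAUCError(VitreoquantError):
    """ROC analysis is impossible because one class is empty."""


class DegenerateImageWarning(UserWarning):
    """A constant (zero-variance) image was pre-processed to all zeros."""


class DegenerateTestWarning(UserWarning):
    """A paired test was degenerate (all differences zero); p set to 1."""
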