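"""Exception hierarchy.

Every error the pipeline can raise deliberately derives from
:class:`AmygconnError` so callers can catch pipeline failures without
swallowing programming errors.
"""


class AmygconnError(Exception):
    """Base class for all pipeline errors."""


class GridError(AmygconnError):
    """A volume's grid (dims / voxel size) does not match what was expected."""


class FormatError(AmygconnError):
    """A file could not be parsed as the expected format."""


class ValidationError(AmygconnError):
    """A table, manifest or configuration failed validation."""


class BandError(AmygconnError):
    """A temporal frequency band is empty or exceeds the Nyquist limit."""


class EmptySeedError(AmygconnError):
    """A seed mask came out empty (unusable subject/seed combination)."""


class DesignError(AmygconnError):
    """A regression design matrix is rank deficient or confounded."""


class SampleSizeError(AmygconnError):
    """Too few subjects (or timepoints) for the requested statistic."""


class ResolutionError(AmygconnError):
    """Monte-Carlo iteration count too small to resolve the requested alpha."""


class EstimationError(AmygconnError):
    """Smoothness (or similar) estimation failed, e.g. mask too small."""


class DegenerateTableError(AmygconnError):
    """A 2x2 contingency table has a zero margin; the chi-square is undefined."""


class SeparationError(AmygconnError):
    """Logistic fit failed to converge for reasons other than separation."""


class FoldError(AmygconnError):
    """A leave-one-out fold could not be completed; carries the fold id."""

    def __init__(self, subject_id, message):
        self.subject_id = subject_id
        super().__init__(f"fold {subject_id!r}: {message}")
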