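"""Exception hierarchy for the cardiovid pipeline.

Every stage raises a subclass of :class:`CardioVidError` so that the CLI can
map any failure to a structured message naming the stage (and chamber, where
one is involved) and a nonzero exit status.
"""


class CardioVidError(Exception):
    """Base class for all cardiovid errors."""


class VideoDecodeError(CardioVidError):
    """The container could not be decoded (corrupt file, unknown format,
    or no decoding backend available for the format)."""


class EmptyVideoError(VideoDecodeError):
    """The container decoded to zero frames."""


class MetadataError(CardioVidError):
    """Required container metadata (fps) is missing and no override was given."""


class ConfigError(CardioVidError):
    """Run configuration is invalid or incomplete (e.g. a missing chamber ROI)."""


class BoundsError(ConfigError):
    """A bounding box does not fit inside the frame."""


class FlatSignalError(CardioVidError):
    """A region-of-interest trace has zero variance — no cardiac motion
    detected in the ROI."""


class TooFewFramesError(CardioVidError):
    """The clip is shorter than the minimum analyzable length (10 frames)."""


class InsufficientBeatsError(CardioVidError):
    """Fewer beats were detected than an interval statistic requires."""


class BandError(CardioVidError):
    """A filter band falls outside the (0, fps/2) Nyquist range."""


class SyntheticSpecError(CardioVidError):
    """A synthetic-clip specification is internally inconsistent."""


class PipelineError(CardioVidError):
    """Wraps a stage failure with stage/chamber identity for reporting."""

    def __init__(self, stage: str, chamber: str | None, cause: Exception):
        self.stage = stage
        self.chamber = chamber
        self.cause = cause
        where = f"stage '{stage}'" + (f", chamber '{chamber}'" if chamber else "")
        super().__init__(f"pipeline failed at {where}: {cause}")
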