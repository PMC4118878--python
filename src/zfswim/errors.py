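"""Exception hierarchy for the zfswim pipeline.

Per-frame problems (a posture that cannot be extracted, a frame with no
detection) are represented as flags or ``None`` entries in the per-frame
results; exceptions are reserved for conditions that invalidate a whole
video, cycle or run.
"""


class ZfswimError(Exception):
    """Base class for all zfswim errors."""


class DecodeError(ZfswimError):
    """A video file or image sequence could not be read."""


class EmptyInputError(ZfswimError):
    """An input that must contain data (frames, records) was empty."""


class ConfigError(ZfswimError):
    """A configuration value violates its documented range."""


class TrackingError(ZfswimError):
    """Fish detection failed in too many frames to continue."""


class PostureError(ZfswimError):
    """A silhouette admits no valid head-to-tail centerline."""


class CycleError(ZfswimError):
    """A body-waving cycle cannot be normalized or analyzed."""


class AnnotationError(ZfswimError):
    """A cycle-annotation file is malformed or out of bounds."""
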