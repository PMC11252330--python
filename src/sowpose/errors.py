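"""Exception hierarchy shared across the package."""


class SowPoseError(Exception):
    """Base class for all package errors."""


class ValidationError(SowPoseError, ValueError):
    """Invalid arguments, malformed tables, broken preconditions."""


class SkeletonError(ValidationError):
    """Unknown skeleton, bad keypoint subset, or view mismatch."""


class ParseError(SowPoseError, ValueError):
    """Malformed annotation / vote / config file; message names the row."""
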