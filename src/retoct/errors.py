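"""Exception hierarchy shared across the pipeline.

Failures that mirror the study's dataset-exclusion policy are typed so the
driver scripts can log them rather than crash: a volume whose flattening or
segmentation fails is *excluded*, never silently degraded.
"""


class RetoctError(Exception):
    """Base class for all pipeline errors."""


class VolumeValidationError(RetoctError, ValueError):
    """A volume, mask, or metadata field violates a structural invariant."""


class ExclusionError(RetoctError):
    """Dataset must be excluded from analysis (e.g. poor SNR, failed flattening)."""


class NoSignalError(RetoctError):
    """Input contains no usable signal (all-zero or below the noise floor)."""


class NoContrastError(RetoctError):
    """Image has no contrast to binarize (constant intensity)."""
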