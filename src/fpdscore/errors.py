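"""Exception hierarchy for the scoring pipeline.

Pipeline stages raise these; :func:`fpdscore.imaging.score_image` catches
them and embeds the class name as a QC flag so no foot is silently dropped.
"""


class FpdError(Exception):
    """Base class for all scoring errors."""


class NoFootDetected(FpdError):
    """No non-background component reaches the minimum area (empty hook)."""


class FootpadNotFound(FpdError):
    """Opened foot mask is empty; no inscribed circle can be placed."""


class DegenerateFootpad(FpdError):
    """Footpad region has zero area; the area ratio is undefined."""


class InvalidThresholds(FpdError):
    """Score thresholds violate the required 0 < t1 < t2 < t3 < 1 ordering."""


class InfeasibleSpec(FpdError):
    """Synthetic-foot spec cannot be rendered on the requested canvas."""


class LevelOutOfRange(FpdError):
    """A rating falls outside the configured level set."""


class DegenerateRatings(FpdError):
    """All ratings identical: expected disagreement is zero, alpha undefined."""


class UndefinedMeasure(FpdError):
    """A performance measure has a zero denominator."""


class MissingTruth(FpdError):
    """Ground truth lacks a mask required by the audit."""
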