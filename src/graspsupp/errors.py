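"""Exception types shared across the pipeline."""


class GraspSuppError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(GraspSuppError):
    """A constrained sequence could not be generated within the retry budget."""


class InvalidMeasureError(GraspSuppError):
    """A kinematic measure could not be computed from the available events/window."""


class MissingDataError(GraspSuppError):
    """A required condition cell has no contributing trials."""


class DegenerateFitError(GraspSuppError):
    """Detection data admit no finite psychometric fit (all-yes/all-no or separable)."""


class ZeroVarianceError(GraspSuppError):
    """A t statistic is undefined because the sample has zero variance."""
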